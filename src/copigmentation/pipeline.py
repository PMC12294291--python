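"""Config-driven orchestration of the short- and long-term analyses.

``run_short_term`` goes from titration inputs (scalar shift tables, full
spectra, or the packaged reference table) to a thermodynamic summary table
plus ln-ln fit and Keq-vs-pH figures.  ``run_long_term`` goes from spectra or
tabulated Lab records to a colour table with sRGB swatches and a 440/510
band-ratio table with ANOVA/Tukey letters.  ``run_simulate`` writes synthetic
fixture CSVs.  Every output table carries a comment header with the package
version and a hash of the configuration, so identical configs and seeds give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .colorimetry import (
    color_from_lab,
    color_from_spectrum,
    load_observer_illuminant,
    load_reference_cielab,
)
from .groupstats import RatioSample, anova_tukey, build_ratio_table, check_assumptions
from .spectra import band_ratio, read_metadata, read_spectra, smooth_savitzky_golay
from .synthetic import GeneratorConfig, generate_titration_spectra
from .thermo import (
    FitSettings,
    TitrationSeries,
    build_thermo_table,
    fit_copigmentation,
    reference_series,
)
from .spectra import write_metadata, write_spectra

__all__ = ["RunConfig", "run_short_term", "run_long_term", "run_simulate"]

log = logging.getLogger("copigmentation")


@dataclass(frozen=True)
class RunConfig:
    """Inputs and settings for one pipeline run."""

    out_dir: str | Path = "results"
    spectra_csv: str | Path | None = None
    metadata_csv: str | Path | None = None
    shifts_csv: str | Path | None = None  # Table-1-style scalar input
    lab_csv: str | Path | None = None  # printed Lab records
    use_reference_fixtures: bool = False
    validate_printed: bool = False
    smooth: bool = True
    sg_window: int = 9
    sg_order: int = 3
    fit: FitSettings = field(default_factory=FitSettings)
    alpha: float = 0.05
    seed: int = 0
    make_plots: bool = True

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # the destination is not part of the analysis identity
        d = {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig, title: str) -> None:
    with open(path, "w") as f:
        f.write(f"# {title}\n")
        f.write(f"# copigmentation {__version__}, config {config.config_hash()}\n")
        df.to_csv(f, index=False)
    log.info("wrote %s (%d rows)", path, len(df))


def _load_series(config: RunConfig) -> list[TitrationSeries]:
    if config.use_reference_fixtures:
        log.info("using packaged reference shift table")
        return reference_series()
    if config.shifts_csv is not None:
        df = pd.read_csv(config.shifts_csv, comment="#")
        ladder_cols = [c for c in df.columns if c.startswith("shift_")]
        from .thermo import REFERENCE_LADDER

        out = []
        for _, row in df.iterrows():
            out.append(
                TitrationSeries.from_shifts(
                    [row[c] for c in ladder_cols],
                    REFERENCE_LADDER[: len(ladder_cols)],
                    copigment=str(row.get("copigment", "none")),
                    pH=float(row.get("pH", 3.6)),
                )
            )
        return out
    if config.spectra_csv is not None:
        meta = (
            read_metadata(config.metadata_csv)
            if config.metadata_csv is not None
            else None
        )
        spectra = read_spectra(config.spectra_csv, metadata=meta)
        if config.smooth:
            spectra = {
                k: smooth_savitzky_golay(s, config.sg_window, config.sg_order)
                for k, s in spectra.items()
            }
        groups: dict[tuple[str, float], dict[str, list]] = {}
        for sid, s in spectra.items():
            key = (s.meta.copigment, s.meta.pH)
            g = groups.setdefault(key, {"ref": [], "obs": []})
            (g["ref"] if s.meta.copigment == "none" or s.meta.molar_ratio is None
             else g["obs"]).append(s)
        out = []
        unresolved = []
        for (cp, pH), g in groups.items():
            if cp == "none":
                continue
            refs = groups.get(("none", pH), {"ref": []})["ref"] or g["ref"]
            if not refs or not g["obs"]:
                unresolved.append(f"{cp}/pH{pH}")
                continue
            # average replicate absorbances at each concentration
            by_conc: dict[float, list] = {}
            for s in g["obs"]:
                by_conc.setdefault(s.meta.copigment_conc, []).append(s)
            from .spectra import absorbance_at

            A0 = float(
                np.mean(
                    [absorbance_at(r, config.fit.lambda_ref) for r in refs]
                )
            )
            obs = tuple(
                sorted(
                    (
                        conc,
                        float(
                            np.mean(
                                [
                                    absorbance_at(s, config.fit.lambda_ref)
                                    for s in ss
                                ]
                            )
                        ),
                    )
                    for conc, ss in by_conc.items()
                )
            )
            out.append(
                TitrationSeries(
                    A0=A0,
                    observations=obs,
                    lambda_ref=config.fit.lambda_ref,
                    copigment=cp,
                    pH=pH,
                )
            )
        if unresolved:
            raise ValueError(
                "unresolvable condition groups (no reference or no titration "
                "spectra): " + ", ".join(sorted(unresolved))
            )
        return out
    raise ValueError(
        "no titration input: set use_reference_fixtures, shifts_csv or spectra_csv"
    )


def run_short_term(config: RunConfig) -> pd.DataFrame:
    """Hyperchromicity fits for every condition; writes the thermo table and,
    optionally, ln-ln fit and Keq-vs-pH figures."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series = _load_series(config)
    log.info("fitting %d titration series", len(series))
    table = build_thermo_table(series, config.fit)
    for _, row in table.iterrows():
        if row["flags"]:
            log.warning(
                "%s pH %.1f: %s", row["copigment"], row["pH"], row["flags"]
            )
    _write_table(
        table, out_dir / "thermo_table.csv", config, "copigmentation thermodynamics"
    )
    if config.make_plots:
        _plot_lnln(series, config, out_dir / "fit_lnln.png")
        _plot_keq_vs_ph(table, out_dir / "keq_vs_ph.png")
    return table


def _plot_lnln(series, config: RunConfig, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for ts in series:
        shifts = ts.shifts
        mask = shifts > 0
        x = np.log(ts.concentrations[mask])
        y = np.log(shifts[mask])
        if mask.sum() < config.fit.min_points:
            continue
        fit = fit_copigmentation(ts, config.fit)
        label = f"{ts.copigment} pH {ts.pH:g} (n={fit.n:.2f})"
        (line,) = ax.plot(x, y, "o", ms=4)
        xs = np.linspace(x.min(), x.max(), 20)
        ax.plot(xs, fit.lnKeq + fit.n * xs, "-", color=line.get_color(), label=label)
    ax.set_xlabel("ln [Cp]$_0$ (mol/L)")
    ax.set_ylabel("ln [(A - A$_0$)/A$_0$]")
    ax.legend(fontsize=6, ncols=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _plot_keq_vs_ph(table: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for cp, grp in table.groupby("copigment"):
        grp = grp.sort_values("pH")
        ax.plot(grp["pH"], grp["Keq"], "o-", label=cp)
    ax.set_xlabel("pH")
    ax.set_ylabel("K$_{eq}$ (M$^{-1}$)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_long_term(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Colour table (with swatches) and band-ratio statistics.

    In ``validate_printed`` mode, C* and H* are recomputed from the tabulated
    a*, b* records and the discrepancies reported; otherwise full spectra are
    converted to CIELab and 440/510 ratios.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}

    if config.validate_printed or config.lab_csv is not None:
        df = (
            pd.read_csv(config.lab_csv, comment="#")
            if config.lab_csv is not None
            else load_reference_cielab()
        )
        rows = []
        for _, r in df.iterrows():
            res = color_from_lab(float(r["L"]), float(r["a"]), float(r["b"]))
            rows.append(
                {
                    "copigment": r.get("copigment", "none"),
                    "pH": r["pH"],
                    "timepoint": r.get("timepoint", ""),
                    "molar_ratio": r.get("molar_ratio", np.nan),
                    "C_printed": r["C"],
                    "C_recomputed": res.C,
                    "C_discrepancy": res.C - float(r["C"]),
                    "H_printed": r["H"],
                    "H_recomputed": res.H,
                    "H_discrepancy": res.H - float(r["H"]),
                    "L": r["L"],
                    "a": r["a"],
                    "b": r["b"],
                    "srgb_hex": res.srgb_hex,
                }
            )
        val = pd.DataFrame(rows)
        _write_table(
            val, out_dir / "color_validation.csv", config, "printed-Lab validation"
        )
        results["color_validation"] = val

    if config.spectra_csv is not None:
        meta = (
            read_metadata(config.metadata_csv)
            if config.metadata_csv is not None
            else None
        )
        spectra = read_spectra(config.spectra_csv, metadata=meta)
        tables = load_observer_illuminant()
        rows = []
        ratio_groups: dict[float, dict[str, list[float]]] = {}
        for sid, s in spectra.items():
            res = color_from_spectrum(s, tables)
            row = {
                "sample_id": sid,
                "copigment": s.meta.copigment,
                "pH": s.meta.pH,
                "timepoint": s.meta.timepoint,
                "molar_ratio": s.meta.molar_ratio,
                "L": res.L,
                "a": res.a,
                "b": res.b,
                "C": res.C,
                "H": res.H,
                "srgb_hex": res.srgb_hex,
            }
            try:
                row["ratio_440_510"] = band_ratio(s)
                if s.meta.molar_ratio is not None:
                    ratio_groups.setdefault(s.meta.pH, {}).setdefault(
                        str(s.meta.molar_ratio), []
                    ).append(row["ratio_440_510"])
            except ValueError as exc:
                row["ratio_440_510"] = np.nan
                log.warning("sample %s: %s", sid, exc)
            rows.append(row)
        color = pd.DataFrame(rows)
        _write_table(color, out_dir / "color_table.csv", config, "CIELab colour table")
        results["color_table"] = color

        stats_rows = {}
        for pH, groups in sorted(ratio_groups.items()):
            samples = [
                RatioSample(label=lab, values=tuple(v), pH=pH)
                for lab, v in sorted(groups.items(), key=lambda kv: int(kv[0]))
                if len(v) >= 2
            ]
            if len(samples) < 2:
                continue
            assumptions = check_assumptions(samples, config.alpha)
            stats_rows[pH] = (samples, anova_tukey(samples, config.alpha, assumptions))
        if stats_rows:
            ratio_table = build_ratio_table(stats_rows)
            _write_table(
                ratio_table,
                out_dir / "ratio_table.csv",
                config,
                "440/510 band-ratio ANOVA/Tukey",
            )
            results["ratio_table"] = ratio_table
    return results


def run_simulate(
    config: RunConfig, generator: GeneratorConfig | None = None
) -> dict[str, Path]:
    """Write synthetic spectra + metadata CSV fixtures for the full design."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gen = generator if generator is not None else GeneratorConfig(seed=config.seed)
    spectra = generate_titration_spectra(gen)
    spath = out_dir / "synthetic_spectra.csv"
    mpath = out_dir / "synthetic_metadata.csv"
    write_spectra(spectra, spath, fmt="long")
    write_metadata(spectra, mpath)
    log.info("wrote %d synthetic spectra to %s", len(spectra), spath)
    return {"spectra": spath, "metadata": mpath}
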