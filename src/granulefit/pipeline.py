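"""Run-level orchestration: sheet → fits → phenotypes → comparisons.

Kept separate from the CLI so the same entry points are scriptable.  Every
run writes its resolved configuration (JSON) and a timestamped plain-text
log next to the output tables, sufficient to re-execute the run.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .distributions import SamplePrep, Weighting, convert_weighting
from .errors import GranulefitError
from .io import SampleSheet, read_sample_sheet, read_trace, write_table
from .mixture import FitOptions, extract_phenotypes, fit_bimodal
from .phenotypes import (DEFAULT_SMALL_THRESHOLD_UM, granules_per_mg,
                         pct_small, summarize_plant)
from .stats import run_comparisons

__all__ = ["FitRunResult", "run_fit", "run_compare", "DEFAULT_PHENOTYPES"]

DEFAULT_PHENOTYPES = ("b_volume_percent", "mean_diam_A_um", "mean_diam_B_um",
                      "granules_per_mg", "pct_small_by_number")

FIT_COLUMNS = ["sample_id", "converged", "n_iter", "rss", "f_B", "mu_A",
               "sigma_A", "mu_B", "sigma_B", "b_volume_percent",
               "mean_diam_A_um", "mean_diam_B_um", "median_diam_A_um",
               "median_diam_B_um", "boundary_flags"]


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.lines: List[str] = []

    def log(self, level: str, msg: str) -> None:
        stamp = _dt.datetime.now().isoformat(timespec="seconds")
        self.lines.append(f"{stamp} {level:7s} {msg}")

    def flush(self) -> None:
        self.path.write_text("\n".join(self.lines) + "\n")


@dataclass
class FitRunResult:
    fits: pd.DataFrame
    sample_phenotypes: pd.DataFrame
    plant_phenotypes: pd.DataFrame
    errors: List[dict] = field(default_factory=list)

    @property
    def status(self) -> int:
        """0 = clean, 3 = partial (some traces failed)."""
        return 0 if not self.errors else 3


def run_fit(sheet: SampleSheet | str | Path, out_dir,
            fit_options: FitOptions = FitOptions(),
            small_threshold: float = DEFAULT_SMALL_THRESHOLD_UM,
            aggregate: bool = True) -> FitRunResult:
    """Fit every trace in the sheet and derive per-sample/per-plant phenotypes.

    Unreadable or invalid traces are recorded and skipped; the run continues
    and finishes with "partial" status instead of aborting.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out_dir / "run.log")
    log.log("INFO", f"granulefit {__version__} fit run")

    if not isinstance(sheet, SampleSheet):
        sheet_path = Path(sheet)
        sheet = read_sample_sheet(sheet_path)
        base_dir = sheet_path.parent
    else:
        base_dir = Path(".")

    fit_rows: List[dict] = []
    grain_records: List[dict] = []
    errors: List[dict] = []
    for _, row in sheet.rows.iterrows():
        sample_id = row["sample_id"]
        trace_path = Path(row["trace_path"])
        if not trace_path.is_absolute():
            trace_path = base_dir / trace_path
        try:
            dist = read_trace(trace_path)
            fit = fit_bimodal(dist, fit_options)
        except (GranulefitError, OSError) as exc:
            log.log("ERROR", f"{sample_id}: {exc}")
            errors.append({"sample_id": sample_id, "error": str(exc)})
            continue
        m = fit.model
        fit_rows.append({
            "sample_id": sample_id, "converged": fit.converged,
            "n_iter": fit.n_iter, "rss": fit.rss, "f_B": m.f_b,
            "mu_A": m.mu_a, "sigma_A": m.sigma_a, "mu_B": m.mu_b,
            "sigma_B": m.sigma_b, "b_volume_percent": 100.0 * m.f_b,
            "mean_diam_A_um": m.mean_diam_a, "mean_diam_B_um": m.mean_diam_b,
            "median_diam_A_um": m.median_diam_a,
            "median_diam_B_um": m.median_diam_b,
            "boundary_flags": ";".join(fit.boundary_flags),
        })
        if not fit.converged:
            log.log("WARNING", f"{sample_id}: fit did not converge")

        record = {"sample_id": sample_id, "genotype": row["genotype"],
                  "plant": row["plant"], "dpa": row.get("dpa", np.nan),
                  "converged": fit.converged}
        if fit.converged:
            record.update(extract_phenotypes(fit))
        try:
            number_dist = convert_weighting(dist, Weighting.NUMBER)
            record["pct_small_by_number"] = pct_small(number_dist,
                                                      small_threshold)
        except GranulefitError as exc:
            log.log("WARNING", f"{sample_id}: pct_small unavailable ({exc})")
        counted = row.get("counted_granules")
        mass = row.get("grain_mass_mg")
        if counted is not None and mass is not None \
                and not (pd.isna(counted) or pd.isna(mass)):
            prep = SamplePrep(aliquot_volume_mL=float(row["aliquot_volume_mL"]),
                              total_volume_mL=float(row["total_volume_mL"]),
                              grain_mass_mg=float(mass),
                              counted_granules=int(counted))
            record["granules_per_mg"] = granules_per_mg(prep)
        grain_records.append(record)

    fits = pd.DataFrame(fit_rows, columns=FIT_COLUMNS)
    samples = pd.DataFrame(grain_records)

    plant_rows = []
    if aggregate and len(samples):
        for key, sub in samples.groupby(["genotype", "plant"], sort=True):
            genotype, plant = key
            dpa_vals = sub["dpa"].dropna().unique() if "dpa" in sub else []
            for dpa in (dpa_vals if len(dpa_vals) else [None]):
                grains = sub if dpa is None else sub[sub["dpa"] == dpa]
                rec = summarize_plant(grains.to_dict("records"),
                                      plant_id=plant, genotype=genotype,
                                      dpa=dpa)
                if rec is None:
                    log.log("WARNING",
                            f"plant {plant} (dpa={dpa}): no converged grains, "
                            "excluded")
                    continue
                plant_rows.append(asdict(rec))
    plants = pd.DataFrame(plant_rows)

    write_table(fits, out_dir / "fits.csv")
    write_table(samples, out_dir / "phenotypes_sample.csv")
    if aggregate:
        write_table(plants, out_dir / "phenotypes.csv")
    config = {
        "version": __version__,
        "fit_options": {k: v for k, v in asdict(fit_options).items()
                        if k != "init"},
        "small_threshold_um": small_threshold,
        "aggregate": aggregate,
        "n_samples": len(sheet), "n_fitted": len(fits),
        "n_errors": len(errors),
    }
    (out_dir / "config.json").write_text(json.dumps(config, indent=2) + "\n")
    if errors:
        (out_dir / "errors.json").write_text(json.dumps(errors, indent=2) + "\n")
    log.log("INFO", f"fitted {len(fits)}/{len(sheet)} traces; "
                    f"{len(errors)} errors")
    log.flush()
    return FitRunResult(fits=fits, sample_phenotypes=samples,
                        plant_phenotypes=plants, errors=errors)


def run_compare(phenotype_table: pd.DataFrame | str | Path, out_dir,
                phenotypes: Optional[Sequence[str]] = None,
                group_col: str = "genotype",
                stratify_by: Optional[str] = None,
                conf: float = 0.95,
                plots: bool = False) -> pd.DataFrame:
    """Genotype comparison tables (and optional forest plots) per phenotype."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out_dir / "compare.log")
    if not isinstance(phenotype_table, pd.DataFrame):
        phenotype_table = pd.read_csv(phenotype_table)
    if group_col not in phenotype_table.columns:
        raise ValueError(f"group column {group_col!r} missing")
    n_groups = phenotype_table[group_col].nunique()
    if n_groups < 2:
        raise ValueError(
            f"need >= 2 groups in {group_col!r}, found {n_groups}; "
            "a comparison requires at least two genotypes")
    if phenotypes is None:
        phenotypes = [p for p in DEFAULT_PHENOTYPES
                      if p in phenotype_table.columns
                      and phenotype_table[p].notna().any()]
    table = run_comparisons(phenotype_table, phenotypes, group_col=group_col,
                            stratify_by=stratify_by, conf=conf)
    for pheno, stratum in table.attrs.get("skipped", []):
        log.log("WARNING", f"skipped {pheno} stratum {stratum!r}: "
                           "fewer than 2 usable groups")
    write_table(table, out_dir / "comparisons.csv")
    meta = {"conf": conf, "group_col": group_col, "stratify_by": stratify_by,
            "phenotypes": list(phenotypes),
            "adjustment": "tukey-within-phenotype-family; no cross-phenotype "
                          "correction"}
    (out_dir / "compare_config.json").write_text(json.dumps(meta, indent=2) + "\n")
    if plots and len(table):
        from .plots import plot_comparisons
        plot_comparisons(table, out_dir / "comparisons.svg")
    log.log("INFO", f"{len(table)} contrasts written")
    log.flush()
    return table
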