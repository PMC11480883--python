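"""Experimental relaxation tables, per-residue pipeline and region summaries.

Reads per-residue ¹⁵N R₂ tables from CSV/TSV or NMR-STAR, runs any of
the τ_eff estimators over them, and aggregates user-supplied
folded/disordered region assignments into per-region statistics with a
Pearson correlation of region size against mean τ_eff.

Input R₂ values are treated as exchange-free R₂° by the single-field
estimators; only the ``rex-corrected`` estimator separates a chemical
exchange contribution, and it needs data at two or more magnetic
fields.  Non-physical or degenerate estimates are flagged, never
clamped, and excluded from region means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from . import nmrstar
from .relaxation_theory import FieldSettings, make_field
from .tau_inversion import (
    TauEffEstimate,
    tau_eff_fitted,
    tau_eff_linear,
    tau_eff_one_timescale,
    tau_eff_rex_corrected,
)

__all__ = [
    "ResidueRelaxationRecord",
    "RegionSummary",
    "Region",
    "SchemaError",
    "read_relaxation_csv",
    "write_relaxation_csv",
    "read_nmrstar_relaxation",
    "per_residue_tau_table",
    "region_summary",
    "ESTIMATORS",
    "FIELD_MATCH_MHZ",
]

logger = logging.getLogger(__name__)

ESTIMATORS = ("linear", "fitted", "one-timescale", "rex-corrected")

#: Records are considered to be at the same field when the proton
#: frequencies agree within this tolerance (BMRB files report e.g. 599.9).
FIELD_MATCH_MHZ = 0.5


class SchemaError(ValueError):
    """A required column is missing or unresolvable."""


@dataclass(frozen=True)
class ResidueRelaxationRecord:
    """One residue's relaxation entry at one magnetic field."""

    residue_number: int
    proton_mhz: float
    r2: float                       # s⁻¹
    residue_name: Optional[str] = None
    r2_err: Optional[float] = None
    r1: Optional[float] = None
    het_noe: Optional[float] = None
    region: Optional[str] = None    # folded | disordered | unassigned

    def field(self) -> FieldSettings:
        return make_field(self.proton_mhz)


@dataclass(frozen=True)
class Region:
    """A contiguous residue span with a folded/disordered class label."""

    label: str
    kind: str                       # "folded" | "disordered"
    first_residue: int
    last_residue: int

    def __post_init__(self) -> None:
        if self.last_residue < self.first_residue:
            raise ValueError("region span must have last >= first")

    @property
    def size(self) -> int:
        return self.last_residue - self.first_residue + 1


@dataclass(frozen=True)
class RegionSummary:
    """Mean/sd of τ_eff over the non-flagged residues of one region."""

    label: str
    kind: str
    first_residue: int
    last_residue: int
    size: int
    n_estimates: int
    mean_tau_ns: float
    sd_tau_ns: float


_CANONICAL_COLUMNS = {
    "residue": "residue",
    "resname": "resname",
    "field_mhz": "field_MHz",
    "r2": "R2",
    "r2_err": "R2_err",
    "r1": "R1",
    "hetnoe": "hetNOE",
    "region": "region",
}


def _resolve_columns(df: pd.DataFrame,
                     column_map: Optional[Mapping[str, str]]
                     ) -> Dict[str, Optional[str]]:
    """Map canonical names (residue, R2, …) to actual dataframe columns."""
    by_lower = {c.lower(): c for c in df.columns}
    resolved: Dict[str, Optional[str]] = {}
    column_map = {k.lower(): v for k, v in (column_map or {}).items()}
    for low, canonical in _CANONICAL_COLUMNS.items():
        if canonical.lower() in column_map:
            actual = column_map[canonical.lower()]
            if actual not in df.columns:
                raise SchemaError(
                    f"mapped column {actual!r} for {canonical!r} not in file"
                )
            resolved[canonical] = actual
        else:
            resolved[canonical] = by_lower.get(low)
    return resolved


def read_relaxation_csv(path, column_map: Optional[Mapping[str, str]] = None,
                        field_mhz: Optional[float] = None,
                        sep: Optional[str] = None
                        ) -> List[ResidueRelaxationRecord]:
    """Read a per-residue relaxation table from CSV/TSV.

    Canonical columns: ``residue``, ``R2`` (required), ``resname``,
    ``field_MHz``, ``R2_err``, ``R1``, ``hetNOE``, ``region``
    (optional); ``column_map`` renames them, ``field_mhz`` supplies
    the field when the file has no per-row column.  Rows with missing
    or non-positive R₂ are skipped with a logged warning.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    cols = _resolve_columns(df, column_map)
    for required in ("residue", "R2"):
        if cols[required] is None:
            raise SchemaError(
                f"required column {required!r} not found in {path} "
                f"(available: {', '.join(map(str, df.columns))})"
            )
    if cols["field_MHz"] is None and field_mhz is None:
        raise SchemaError(
            "no field_MHz column and no field_mhz override given; the "
            "magnetic field (proton MHz) is required"
        )

    records: List[ResidueRelaxationRecord] = []
    n_skipped = 0
    for _, row in df.iterrows():
        r2 = row[cols["R2"]]
        if pd.isna(r2) or not math.isfinite(float(r2)) or float(r2) <= 0:
            n_skipped += 1
            logger.warning("skipping residue %s: invalid R2 %r",
                           row[cols["residue"]], r2)
            continue

        def opt(name, cast=float):
            col = cols[name]
            if col is None or pd.isna(row[col]):
                return None
            return cast(row[col])

        mhz = opt("field_MHz")
        records.append(ResidueRelaxationRecord(
            residue_number=int(row[cols["residue"]]),
            residue_name=opt("resname", str),
            proton_mhz=float(mhz if mhz is not None else field_mhz),
            r2=float(r2),
            r2_err=opt("R2_err"),
            r1=opt("R1"),
            het_noe=opt("hetNOE"),
            region=opt("region", str),
        ))
    if n_skipped:
        logger.warning("%d row(s) skipped for missing/non-positive R2",
                       n_skipped)
    return records


def write_relaxation_csv(path, records: Iterable[ResidueRelaxationRecord],
                         sep: str = ",") -> None:
    """Write records back to CSV with the canonical column names."""
    rows = [{
        "residue": r.residue_number,
        "resname": r.residue_name,
        "field_MHz": r.proton_mhz,
        "R2": r.r2,
        "R2_err": r.r2_err,
        "R1": r.r1,
        "hetNOE": r.het_noe,
        "region": r.region,
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False,
                              float_format="%.12g")


def read_nmrstar_relaxation(path, field_mhz: Optional[float] = None
                            ) -> List[ResidueRelaxationRecord]:
    """Read heteronuclear T₂/R₂ save-frames from an NMR-STAR file.

    T₂ values (seconds) are converted to R₂ = 1/T₂; zero or negative
    entries are skipped with a warning.  A file lacking the
    spectrometer frequency raises unless ``field_mhz`` is given.
    """
    frames = nmrstar.read_star_file(path)
    t2_frames = nmrstar.find_t2_saveframes(frames)
    if not t2_frames:
        raise ValueError(
            f"{path}: no heteronuclear T2/R2 relaxation save-frame found"
        )
    records: List[ResidueRelaxationRecord] = []
    for frame in t2_frames:
        freq, kind, rows = nmrstar.extract_t2_rows(frame)
        if freq is None:
            if field_mhz is None:
                raise ValueError(
                    f"{path}: save-frame {frame.name!r} does not state the "
                    "spectrometer frequency; pass field_mhz (CLI: --field) "
                    "to override"
                )
            freq = field_mhz
        for row in rows:
            value, err = row["value"], row["err"]
            if kind == "T2":
                if value <= 0:
                    logger.warning("skipping residue %s: non-positive T2 %r",
                                   row["seq"], value)
                    continue
                r2 = 1.0 / value
                r2_err = err / value ** 2 if err is not None else None
            else:
                if value <= 0:
                    logger.warning("skipping residue %s: non-positive R2 %r",
                                   row["seq"], value)
                    continue
                r2, r2_err = value, err
            records.append(ResidueRelaxationRecord(
                residue_number=row["seq"], residue_name=row["comp"],
                proton_mhz=float(freq), r2=r2, r2_err=r2_err,
            ))
    return records


def _group_fields(records: Sequence[ResidueRelaxationRecord]
                  ) -> Dict[float, List[ResidueRelaxationRecord]]:
    """Group records into fields, merging frequencies within 0.5 MHz."""
    groups: Dict[float, List[ResidueRelaxationRecord]] = {}
    for rec in records:
        for key in groups:
            if abs(key - rec.proton_mhz) <= FIELD_MATCH_MHZ:
                groups[key].append(rec)
                break
        else:
            groups[rec.proton_mhz] = [rec]
    return groups


def per_residue_tau_table(records: Sequence[ResidueRelaxationRecord],
                          estimator: str = "linear") -> pd.DataFrame:
    """Estimate τ_eff for every residue (and field) in a record list.

    Returns a dataframe with columns residue, resname, field_MHz,
    R2, tau_eff_ns, tau_err_ns, rex_s, estimator, flag, region.
    Single-field estimators produce one row per record; the
    rex-corrected estimator pools each residue's fields into one row
    (field_MHz = "multi") and additionally reports the fitted exchange
    rate at the lowest field.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from "
                         f"{', '.join(ESTIMATORS)}")
    if not records:
        return pd.DataFrame(columns=[
            "residue", "resname", "field_MHz", "R2", "tau_eff_ns",
            "tau_err_ns", "rex_s", "estimator", "flag", "region"])

    rows = []
    if estimator == "rex-corrected":
        by_residue: Dict[int, List[ResidueRelaxationRecord]] = {}
        for rec in records:
            by_residue.setdefault(rec.residue_number, []).append(rec)
        for resnum in sorted(by_residue):
            recs = by_residue[resnum]
            groups = _group_fields(recs)
            if len(groups) < 2:
                raise ValueError(
                    f"residue {resnum}: rex-corrected estimator needs R2 at "
                    f">= 2 distinct fields, got {len(groups)}"
                )
            est = tau_eff_rex_corrected(
                [(rec.r2, rec.field()) for rec in recs])
            rex_ref = min(est.rex_by_field.items())[1] \
                if est.rex_by_field else None
            rows.append({
                "residue": resnum,
                "resname": recs[0].residue_name,
                "field_MHz": "multi",
                "R2": np.nan,
                "tau_eff_ns": est.tau_eff * 1e9,
                "tau_err_ns": np.nan,
                "rex_s": rex_ref,
                "estimator": est.estimator,
                "flag": est.flag,
                "region": recs[0].region,
            })
    else:
        for rec in records:
            est = _single_field_estimate(rec, estimator)
            rows.append({
                "residue": rec.residue_number,
                "resname": rec.residue_name,
                "field_MHz": rec.proton_mhz,
                "R2": rec.r2,
                "tau_eff_ns": est.tau_eff * 1e9,
                "tau_err_ns": (est.tau_err * 1e9
                               if est.tau_err is not None else np.nan),
                "rex_s": np.nan,
                "estimator": est.estimator,
                "flag": est.flag,
                "region": rec.region,
            })
    return pd.DataFrame(rows)


def _single_field_estimate(rec: ResidueRelaxationRecord,
                           estimator: str) -> TauEffEstimate:
    if estimator == "linear":
        return tau_eff_linear(rec.r2, rec.field(), r2_err=rec.r2_err)
    if estimator == "fitted":
        return tau_eff_fitted(rec.r2, rec.proton_mhz)
    if estimator == "one-timescale":
        return tau_eff_one_timescale(rec.r2, rec.field())
    raise ValueError(estimator)  # pragma: no cover


def region_summary(tau_table: pd.DataFrame,
                   regions: Sequence[Region]
                   ) -> Tuple[List[RegionSummary],
                              Dict[str, Optional[Tuple[float, float]]]]:
    """Aggregate a τ_eff table over folded/disordered regions.

    Per region: mean and sd of τ_eff over non-flagged residues in the
    span.  Per region class (folded, disordered): Pearson correlation
    (r, two-sided p) between region size and region mean τ_eff across
    that class's regions; ``None`` when fewer than 3 regions make the
    correlation undefined.
    """
    seen: Dict[int, str] = {}
    for region in regions:
        for resnum in range(region.first_residue, region.last_residue + 1):
            if resnum in seen:
                raise ValueError(
                    f"residue {resnum} assigned to both {seen[resnum]!r} "
                    f"and {region.label!r}"
                )
            seen[resnum] = region.label

    ok = tau_table[tau_table["flag"].isna()] \
        if "flag" in tau_table.columns else tau_table
    summaries: List[RegionSummary] = []
    for region in regions:
        mask = ok["residue"].between(region.first_residue,
                                     region.last_residue)
        taus = ok.loc[mask, "tau_eff_ns"].to_numpy(dtype=float)
        mean = float(np.mean(taus)) if taus.size else math.nan
        sd = float(np.std(taus, ddof=1)) if taus.size > 1 else 0.0
        summaries.append(RegionSummary(
            label=region.label, kind=region.kind,
            first_residue=region.first_residue,
            last_residue=region.last_residue,
            size=region.size, n_estimates=int(taus.size),
            mean_tau_ns=mean, sd_tau_ns=sd,
        ))

    correlations: Dict[str, Optional[Tuple[float, float]]] = {}
    for kind in sorted({s.kind for s in summaries}):
        pts = [(s.size, s.mean_tau_ns) for s in summaries
               if s.kind == kind and not math.isnan(s.mean_tau_ns)]
        if len(pts) < 3:
            correlations[kind] = None
            continue
        sizes, means = zip(*pts)
        result = pearsonr(sizes, means)
        correlations[kind] = (float(result.statistic), float(result.pvalue))
    return summaries, correlations
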