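"""Reading search-engine glyco-PSM exports and collapsing them to unique
glycopeptides.

The expected input dialect is a tab-separated PSM table in the style of
open-search exports (one row per peptide-spectrum match) carrying the peptide
sequence, protein accession, glycosite position, assigned glycan composition,
the glycan q-value, the MS1 precursor intensity and optionally TMT reporter
columns.  Column names are configurable through :class:`ColumnMap`.

Identification-level filters applied here:

* glycan q-value cutoff (default 0.05),
* for O-glycan data, removal of peptides containing the N-glycosylation
  sequon N-X-S/T (to prevent N/O misassignment) and of peptides without a
  target match,
* collapse of PSMs to unique glycopeptides, where a unique glycopeptide is a
  unique peptide sequence combined with a unique glycan composition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glycans import GlycanComposition, GlycanParseError, parse_composition
from .matrix import IntensityMatrix

__all__ = [
    "ColumnMap",
    "GlycoPSM",
    "GlycopeptideRecord",
    "read_psm_table",
    "write_psm_table",
    "qc_filter",
    "collapse_unique",
    "records_to_frame",
    "mask_channel_leak",
    "NO_TARGET_TOKENS",
]


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from logical fields to column names of the PSM export."""

    peptide: str = "Peptide"
    protein: str = "Protein ID"
    site: str = "Site Position"
    composition: str = "Glycan Composition"
    glycan_q: str = "Glycan q-value"
    intensity: str = "Intensity"
    spectrum: str = "Spectrum"
    protein_match: str = "Protein ID"  # column checked for a target match
    reporter_prefix: str = "channel_"


#: Values of the protein column that mean "no target match" in search exports.
NO_TARGET_TOKENS = frozenset({"", "na", "nan", "none", "no_match", "unmatched"})


@dataclass(frozen=True)
class GlycoPSM:
    peptide: str
    protein: str
    site_position: int
    composition: GlycanComposition
    glycan_q: float
    ms1_intensity: float
    reporter_intensities: tuple[float, ...] = ()
    spectrum_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.glycan_q <= 1.0):
            raise ValueError(f"glycan_q {self.glycan_q} outside [0, 1]")
        if self.site_position < 1:
            raise ValueError(f"site_position {self.site_position} must be >= 1")


@dataclass(frozen=True)
class GlycopeptideRecord:
    """One unique glycopeptide: (peptide sequence, glycan composition)."""

    peptide: str
    protein: str
    site_position: int
    composition: GlycanComposition
    ms1_intensity: float
    reporter_intensities: tuple[float, ...]
    n_psms: int

    @property
    def feature_id(self) -> str:
        return f"{self.peptide}|{self.composition}"

    @property
    def site_id(self) -> str:
        return f"{self.protein}|{self.site_position}"


def read_psm_table(path, mode: str = "N", columns: ColumnMap | None = None):
    """Read a tab-separated PSM export into :class:`GlycoPSM` records.

    Rows with no glycan assignment (empty composition cell) are dropped and
    counted; rows that fail to parse are reported with their line numbers.
    Returns ``(psms, report)`` where ``report`` is a dict with keys
    ``n_rows``, ``n_parsed``, ``n_no_glycan``, ``malformed`` (list of
    ``(line_number, message)``), and ``reporter_columns``.
    """
    if mode not in ("N", "O"):
        raise ValueError(f"mode must be 'N' or 'O', got {mode!r}")
    cmap = columns or ColumnMap()
    df = pd.read_csv(path, sep="\t", dtype=str)
    mandatory = [cmap.peptide, cmap.protein, cmap.site, cmap.composition, cmap.glycan_q]
    for col in mandatory:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r} in {path}")
    reporter_cols = [c for c in df.columns if c.startswith(cmap.reporter_prefix)]
    psms: list[GlycoPSM] = []
    report = {
        "n_rows": len(df),
        "n_parsed": 0,
        "n_no_glycan": 0,
        "malformed": [],
        "reporter_columns": reporter_cols,
    }
    for i, row in df.iterrows():
        line_no = i + 2  # 1-based, after header
        comp_text = row[cmap.composition]
        if pd.isna(comp_text) or not str(comp_text).strip():
            report["n_no_glycan"] += 1
            continue
        try:
            comp = parse_composition(str(comp_text))
            reporters = tuple(
                float(row[c]) if pd.notna(row[c]) else np.nan for c in reporter_cols
            )
            psms.append(
                GlycoPSM(
                    peptide=str(row[cmap.peptide]),
                    protein=str(row[cmap.protein]),
                    site_position=int(float(row[cmap.site])),
                    composition=comp,
                    glycan_q=float(row[cmap.glycan_q]),
                    ms1_intensity=(
                        float(row[cmap.intensity])
                        if cmap.intensity in df.columns and pd.notna(row[cmap.intensity])
                        else np.nan
                    ),
                    reporter_intensities=reporters,
                    spectrum_id=(
                        str(row[cmap.spectrum]) if cmap.spectrum in df.columns else ""
                    ),
                )
            )
            report["n_parsed"] += 1
        except (GlycanParseError, ValueError) as exc:
            report["malformed"].append((line_no, str(exc)))
    return psms, report


def write_psm_table(psms: list[GlycoPSM], path, columns: ColumnMap | None = None) -> None:
    """Write PSMs back in the same tab-separated dialect (round-trippable)."""
    cmap = columns or ColumnMap()
    n_rep = max((len(p.reporter_intensities) for p in psms), default=0)
    rows = []
    for p in psms:
        row = {
            cmap.peptide: p.peptide,
            cmap.protein: p.protein,
            cmap.site: p.site_position,
            cmap.composition: str(p.composition),
            cmap.glycan_q: p.glycan_q,
            cmap.intensity: p.ms1_intensity,
            cmap.spectrum: p.spectrum_id,
        }
        for j in range(n_rep):
            row[f"{cmap.reporter_prefix}{j + 1}"] = (
                p.reporter_intensities[j] if j < len(p.reporter_intensities) else np.nan
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_SEQUON_ANY = re.compile(r"N.[ST]")
_SEQUON_NO_PRO = re.compile(r"N[^P][ST]")


def qc_filter(
    psms: list[GlycoPSM],
    mode: str = "N",
    q_max: float = 0.05,
    sequon_exclude_proline: bool = False,
):
    """Apply identification-confidence filters.

    Keeps PSMs with ``glycan_q <= q_max``.  In O mode additionally drops
    peptides whose sequence contains the N-sequon N-X-S/T (any X by default;
    X != P when ``sequon_exclude_proline``) and PSMs without a target match.
    Returns ``(kept, report)`` with per-reason drop counts.
    """
    if mode not in ("N", "O"):
        raise ValueError(f"mode must be 'N' or 'O', got {mode!r}")
    sequon = _SEQUON_NO_PRO if sequon_exclude_proline else _SEQUON_ANY
    kept: list[GlycoPSM] = []
    report = {"n_input": len(psms), "q_value": 0, "sequon": 0, "no_target": 0}
    for p in psms:
        if p.glycan_q > q_max:
            report["q_value"] += 1
            continue
        if mode == "O":
            if p.protein.strip().lower() in NO_TARGET_TOKENS:
                report["no_target"] += 1
                continue
            if sequon.search(p.peptide):
                report["sequon"] += 1
                continue
        kept.append(p)
    report["n_output"] = len(kept)
    return kept, report


def collapse_unique(
    psms: list[GlycoPSM],
    ms1_agg: str = "max",
    reporter_agg: str = "sum",
) -> list[GlycopeptideRecord]:
    """Collapse PSMs to unique glycopeptides keyed by (peptide, composition).

    MS1 intensity aggregates by max (peak-height proxy; ``ms1_agg='sum'``
    available) and reporter vectors element-wise by sum (additive ion counts;
    ``reporter_agg='mean'`` available).  PSMs in one group must agree on the
    site position, otherwise a ValueError lists the conflicting group.
    """
    if ms1_agg not in ("max", "sum"):
        raise ValueError(f"ms1_agg must be 'max' or 'sum', got {ms1_agg!r}")
    if reporter_agg not in ("sum", "mean"):
        raise ValueError(f"reporter_agg must be 'sum' or 'mean', got {reporter_agg!r}")
    groups: dict[tuple[str, GlycanComposition], list[GlycoPSM]] = {}
    for p in psms:
        groups.setdefault((p.peptide, p.composition), []).append(p)
    records = []
    for (peptide, comp), members in groups.items():
        sites = {(m.protein, m.site_position) for m in members}
        if len(sites) > 1:
            raise ValueError(
                f"conflicting site assignment for glycopeptide ({peptide}, {comp}): {sorted(sites)}"
            )
        protein, site = next(iter(sites))
        ms1 = [m.ms1_intensity for m in members if np.isfinite(m.ms1_intensity)]
        agg_ms1 = (max(ms1) if ms1_agg == "max" else sum(ms1)) if ms1 else np.nan
        reps = np.array([m.reporter_intensities for m in members], dtype=float)
        if reps.size:
            agg_rep = np.nansum(reps, axis=0) if reporter_agg == "sum" else np.nanmean(reps, axis=0)
            agg_rep = tuple(agg_rep.tolist())
        else:
            agg_rep = ()
        records.append(
            GlycopeptideRecord(
                peptide=peptide,
                protein=protein,
                site_position=site,
                composition=comp,
                ms1_intensity=agg_ms1,
                reporter_intensities=agg_rep,
                n_psms=len(members),
            )
        )
    return records


def records_to_frame(records: list[GlycopeptideRecord]) -> pd.DataFrame:
    """Tabulate unique-glycopeptide records (one row per record)."""
    rows = []
    for r in records:
        row = {
            "feature_id": r.feature_id,
            "peptide": r.peptide,
            "protein": r.protein,
            "site_position": r.site_position,
            "composition": str(r.composition),
            "ms1_intensity": r.ms1_intensity,
            "n_psms": r.n_psms,
        }
        for j, v in enumerate(r.reporter_intensities):
            row[f"channel_{j + 1}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def mask_channel_leak(matrix: IntensityMatrix, ratio: float = 1.0 / 16.0, drop_feature: bool = False):
    """Mask reporter signals attributable to TMT channel leak.

    Per feature, channels with intensity strictly below ``ratio`` times the
    feature's maximum channel are set to missing (a channel exactly at the
    boundary is retained).  Features whose channels are all masked or all
    zero/missing are dropped.  With ``drop_feature=True`` any feature with at
    least one leaking channel is removed entirely instead of masked.

    Returns ``(masked_matrix, report)``; the operation is idempotent.
    """
    if matrix.scale != "raw":
        raise ValueError("channel-leak masking operates on raw intensities")
    v = matrix.values.to_numpy(dtype=float, copy=True)
    with np.errstate(invalid="ignore"):
        vmax = np.nanmax(np.where(np.isfinite(v), v, -np.inf), axis=1)
    dead = ~np.isfinite(vmax) | (vmax <= 0)
    leak = np.isfinite(v) & (v < ratio * vmax[:, None])
    n_masked = int(leak.sum())
    v[leak] = np.nan
    all_masked = ~np.isfinite(v).any(axis=1)
    if drop_feature:
        drop = dead | all_masked | leak.any(axis=1)
    else:
        drop = dead | all_masked
    out = pd.DataFrame(v, index=matrix.values.index, columns=matrix.values.columns).loc[~drop]
    report = {
        "n_channels_masked": n_masked,
        "n_features_dropped": int(drop.sum()),
        "dropped_features": matrix.values.index[drop].tolist(),
    }
    return matrix.with_values(out), report
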