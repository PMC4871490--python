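"""CSV readers/writers, column mapping and report rendering.

The canonical interchange schema is a pair of tables:

* tree table: ``tree_id, forest_type, species, dbh_cm, ht_m``
* section table: ``tree_id, stem_id, h_m, d_cm``

``ColumnMapping`` absorbs datasets with other headers or units.  Section rows
violating the stem invariants (non-positive diameter, non-increasing heights,
heights at or above the total height) are rejected row-by-row with a
diagnostic rather than failing the whole load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stem_geometry import FOREST_TYPES, StemMeasurement, StemProfile, Tree

__all__ = [
    "ColumnMapping",
    "DEFAULT_MAPPING",
    "InventoryReadResult",
    "read_inventory",
    "write_inventory",
    "run_report",
]

log = logging.getLogger(__name__)

_LENGTH_FACTORS = {"m": 1.0, "cm": 0.01, "mm": 0.001}
_DIAMETER_FACTORS = {"cm": 1.0, "mm": 0.1, "m": 100.0}

_FOREST_ALIASES = {
    "cerrado": "cerrado",
    "semideciduous": "semideciduous",
    "semi-deciduous": "semideciduous",
    "semi_deciduous": "semideciduous",
    "semi-deciduous forest": "semideciduous",
    "rainforest": "rainforest",
    "rain forest": "rainforest",
}


@dataclass(frozen=True)
class ColumnMapping:
    """Source-column names and units for the tree and section tables."""

    tree_columns: dict = field(default_factory=lambda: {
        "tree_id": "tree_id", "forest_type": "forest_type",
        "species": "species", "dbh": "dbh_cm", "ht": "ht_m",
    })
    section_columns: dict = field(default_factory=lambda: {
        "tree_id": "tree_id", "stem_id": "stem_id", "h": "h_m", "d": "d_cm",
    })
    height_unit: str = "m"
    diameter_unit: str = "cm"

    def __post_init__(self):
        if self.height_unit not in _LENGTH_FACTORS:
            raise ValueError(f"unsupported height unit {self.height_unit!r}")
        if self.diameter_unit not in _DIAMETER_FACTORS:
            raise ValueError(f"unsupported diameter unit {self.diameter_unit!r}")


DEFAULT_MAPPING = ColumnMapping()


@dataclass
class InventoryReadResult:
    trees: list[Tree]
    n_rejected_rows: int
    diagnostics: list[str]


def _require_columns(frame: pd.DataFrame, needed: dict, table: str):
    missing = [src for src in needed.values() if src not in frame.columns]
    if missing:
        raise ValueError(f"{table} table is missing columns {missing}")


def normalize_forest_type(value: str) -> str:
    key = str(value).strip().lower()
    if key not in _FOREST_ALIASES:
        raise ValueError(
            f"unknown forest type {value!r}; expected one of {FOREST_TYPES}"
        )
    return _FOREST_ALIASES[key]


def read_inventory(
    tree_csv, section_csv, mapping: ColumnMapping | None = None
) -> InventoryReadResult:
    """Load and validate a tree + section CSV pair into Tree objects.

    Rows violating stem invariants are dropped with a per-row diagnostic;
    stems left with fewer than two valid measurements, and trees left with
    no stems, are dropped likewise.
    """
    mapping = mapping or DEFAULT_MAPPING
    trees_df = pd.read_csv(tree_csv, float_precision="round_trip")
    sections_df = pd.read_csv(section_csv, float_precision="round_trip")
    if trees_df.empty:
        raise ValueError(f"tree table {tree_csv} is empty")
    if sections_df.empty:
        raise ValueError(f"section table {section_csv} is empty")
    _require_columns(trees_df, mapping.tree_columns, "tree")
    _require_columns(sections_df, mapping.section_columns, "section")

    tc, sc = mapping.tree_columns, mapping.section_columns
    h_factor = _LENGTH_FACTORS[mapping.height_unit]
    d_factor = _DIAMETER_FACTORS[mapping.diameter_unit]

    diagnostics: list[str] = []
    n_rejected = 0
    trees: list[Tree] = []

    sections_by_tree = dict(tuple(sections_df.groupby(sections_df[sc["tree_id"]])))

    for _, trow in trees_df.iterrows():
        tree_id = str(trow[tc["tree_id"]])
        try:
            forest = normalize_forest_type(trow[tc["forest_type"]])
        except ValueError as exc:
            diagnostics.append(f"tree {tree_id}: {exc}")
            continue
        dbh = float(trow[tc["dbh"]]) * d_factor
        ht = float(trow[tc["ht"]]) * h_factor
        tree_sections = sections_by_tree.get(tree_id)
        if tree_sections is None:
            diagnostics.append(f"tree {tree_id}: no section rows")
            continue
        stems = []
        for stem_id, srows in tree_sections.groupby(tree_sections[sc["stem_id"]]):
            srows = srows.sort_values(sc["h"])
            measurements = []
            prev_h = -np.inf
            for _, srow in srows.iterrows():
                h = float(srow[sc["h"]]) * h_factor
                d = float(srow[sc["d"]]) * d_factor
                if d <= 0:
                    n_rejected += 1
                    diagnostics.append(
                        f"tree {tree_id} stem {stem_id}: rejected row "
                        f"h={h:g} (non-positive diameter {d:g})")
                    continue
                if h >= ht:
                    n_rejected += 1
                    diagnostics.append(
                        f"tree {tree_id} stem {stem_id}: rejected row "
                        f"h={h:g} (at or above total height {ht:g})")
                    continue
                if h <= prev_h:
                    n_rejected += 1
                    diagnostics.append(
                        f"tree {tree_id} stem {stem_id}: rejected row "
                        f"h={h:g} (heights not increasing)")
                    continue
                measurements.append(StemMeasurement(h, d))
                prev_h = h
            if len(measurements) < 2:
                diagnostics.append(
                    f"tree {tree_id} stem {stem_id}: dropped "
                    f"({len(measurements)} valid measurements)")
                continue
            stems.append(StemProfile(str(stem_id), tuple(measurements)))
        if not stems:
            diagnostics.append(f"tree {tree_id}: dropped (no valid stems)")
            continue
        trees.append(Tree(tree_id=tree_id, forest_type=forest,
                          species=str(trow[tc["species"]]), dbh=dbh, ht=ht,
                          stems=tuple(stems)))
    log.info("read %d trees (%d rows rejected, %d diagnostics)",
             len(trees), n_rejected, len(diagnostics))
    return InventoryReadResult(trees, n_rejected, diagnostics)


def write_inventory(trees, tree_csv, section_csv) -> None:
    """Write trees to the canonical CSV pair (floats at full precision)."""
    tree_records = [
        (t.tree_id, t.forest_type, t.species, repr(t.dbh), repr(t.ht))
        for t in trees
    ]
    section_records = [
        (t.tree_id, s.stem_id, repr(m.h), repr(m.d))
        for t in trees for s in t.stems for m in s.measurements
    ]
    pd.DataFrame(tree_records, columns=[
        "tree_id", "forest_type", "species", "dbh_cm", "ht_m"
    ]).to_csv(tree_csv, index=False)
    pd.DataFrame(section_records, columns=[
        "tree_id", "stem_id", "h_m", "d_cm"
    ]).to_csv(section_csv, index=False)


def run_report(cv_summary: pd.DataFrame | None, fits: dict | None,
               tally, outdir) -> Path:
    """Render the pipeline outputs as deterministic CSV + text files.

    ``fits`` maps forest -> model name -> TaperFit.  Non-converged fits
    render as "no convergence" rather than numbers.  Returns the path of the
    text report.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["stem taper run report", "=" * 40]

    if fits is not None:
        fit_records = []
        lines.append("\nTaper model AICc per forest type:")
        for forest in sorted(fits):
            for name, fit in fits[forest].items():
                score = f"{fit.aicc:.2f}" if fit.converged else "no convergence"
                lines.append(f"  {forest:15s} {name:14s} {score}")
                fit_records.append({
                    "forest_type": forest, "model": name,
                    "converged": fit.converged,
                    "aicc": fit.aicc if fit.converged else "",
                    "sse": fit.sse, "n_obs": fit.n_obs,
                    **{f"beta{i + 1}": b for i, b in enumerate(fit.beta)},
                })
        pd.DataFrame(fit_records).to_csv(outdir / "taper_fits.csv", index=False)

    if tally is not None:
        lines.append("\nLowest-AICc winners:")
        for forest in sorted(tally.winners):
            tie = " (tie)" if forest in tally.ties else ""
            lines.append(f"  {forest:15s} {', '.join(tally.winners[forest])}{tie}")
        for forest in tally.excluded_forests:
            lines.append(f"  {forest:15s} no convergence for any model")
        lines.append(f"  overall best: {', '.join(tally.overall_best) or 'none'}")
        pd.DataFrame(
            [(m, c) for m, c in sorted(tally.counts.items())],
            columns=["model", "wins"],
        ).to_csv(outdir / "tally.csv", index=False)

    if cv_summary is not None:
        lines.append("\nCross-validation summary (means over iterations):")
        lines.append(cv_summary.to_string(index=False, float_format="%.4f"))
        cv_summary.to_csv(outdir / "cv_summary.csv", index=False)

    report_path = outdir / "report.txt"
    report_path.write_text("\n".join(lines) + "\n")
    return report_path
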