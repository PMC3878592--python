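"""Human- and tool-readable outputs.

Covers the variance-decomposition summary (percent of each block's
variation that is globally joint, locally joint, unique or residual),
merged direction-arrow tables across molecular levels, and export files
for the external pathway-painting viewers (MapMan-style two-column
identifier/value files and Paintomics-style multi-column matrices).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .onpls import OnPLSModel
from .selection import SignificanceTable

logger = logging.getLogger("onplskit")

_ARROW = {1: "up", -1: "down", 0: "-"}


def r2_report(model: OnPLSModel) -> pd.DataFrame:
    """One row per block with percentages to one decimal.

    The residual column is set to 100 minus the other rounded entries, so
    every row sums to exactly 100.0 despite rounding.
    """
    frame = model.r2.as_frame() * 100.0
    out = frame.round(1)
    other = [c for c in out.columns if c != "residual"]
    out["residual"] = (100.0 - out[other].sum(axis=1)).round(1)
    return out


def r2_report_from_fractions(fractions: pd.DataFrame) -> pd.DataFrame:
    """Same formatting applied to an already-loaded fraction table."""
    out = (fractions * 100.0).round(1)
    other = [c for c in out.columns if c != "residual"]
    out["residual"] = (100.0 - out[other].sum(axis=1)).round(1)
    return out


def merged_arrow_table(
    tables: Sequence[SignificanceTable],
    id_mapping: Mapping[str, Mapping[str, str]] | None = None,
    annotations: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Merge per-block significance into one arrow table.

    ``id_mapping`` maps a block name to {feature_id_in_first_table ->
    id_in_that_block}; the first table's ids anchor the rows.  Each block
    contributes one ``<block>_<line>`` column rendered as ``up``/``down``/
    ``-``.  Rows are sorted by annotation label (default: the id itself),
    then id.
    """
    if not tables:
        return pd.DataFrame()
    id_mapping = id_mapping or {}
    annotations = annotations or {}
    anchor = tables[0]
    rows = []
    for fid in anchor.table.index:
        row: dict = {
            "feature_id": fid,
            "annotation": annotations.get(fid, fid),
        }
        keep = False
        for tbl in tables:
            mapping = id_mapping.get(tbl.block)
            if tbl is anchor:
                mapped = fid
            elif mapping is not None:
                mapped = mapping.get(fid)
            else:
                mapped = fid if fid in tbl.table.index else None
            if mapping is not None:
                dup = [k for k, v in mapping.items() if v == mapped and k != fid]
                if mapped is not None and dup:
                    raise ValueError(
                        f"duplicate mapping target {mapped!r} in block {tbl.block!r}"
                    )
            for line in tbl.lines:
                col = f"{tbl.block}_{line}"
                if mapped is not None and mapped in tbl.table.index:
                    d = int(tbl.table.at[mapped, f"dir_{line}"])
                else:
                    d = 0
                row[col] = _ARROW[d]
                keep = keep or d != 0
        if keep:
            rows.append(row)
    columns = ["feature_id", "annotation"] + [
        f"{tbl.block}_{line}" for tbl in tables for line in tbl.lines
    ]
    out = pd.DataFrame(rows, columns=columns)
    return out.sort_values(["annotation", "feature_id"]).reset_index(drop=True)


def export_mapman(
    table: SignificanceTable,
    out_dir: str | Path,
    values: str = "direction",
) -> list[Path]:
    """Write one two-column (IDENTIFIER, VALUE) file per non-reference line.

    Only significant variables are exported; identifiers are lower-cased.
    ``values`` picks the VALUE column: ``direction`` (+/-1), ``mean_scaled``
    (the line's mean WT-scaled value, 6 decimals) or ``loading`` (the
    dominant global loading).
    """
    if values not in ("direction", "mean_scaled", "loading"):
        raise ValueError(f"unknown value mode {values!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sig = table.table[table.table["significant"]]
    if sig.empty:
        logger.warning("block %r: no significant variables; MapMan files will be empty",
                       table.block)
    paths = []
    for line in table.lines:
        path = out_dir / f"mapman_{table.block}_{line}.txt"
        with open(path, "w") as fh:
            fh.write("IDENTIFIER\tVALUE\n")
            for fid, row in sig.iterrows():
                if values == "direction":
                    val = f"{int(row[f'dir_{line}']):d}"
                elif values == "mean_scaled":
                    val = f"{row[f'mean_{line}']:.6f}"
                else:
                    val = f"{row['theta']:.6f}"
                fh.write(f"{str(fid).lower()}\t{val}\n")
        paths.append(path)
    return paths


def export_paintomics(
    tables: Sequence[SignificanceTable],
    out_dir: str | Path,
) -> list[Path]:
    """Write one multi-column TSV per molecular level (block).

    First column: feature id; one numeric column per non-reference line
    holding the line's mean WT-scaled value.  All variables are exported
    (the viewer does its own thresholding on colour scales).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for tbl in tables:
        path = out_dir / f"paintomics_{tbl.block}.tsv"
        cols = {f"{line}": tbl.table[f"mean_{line}"] for line in tbl.lines}
        out = pd.DataFrame(cols)
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t", float_format="%.6f")
        paths.append(path)
    return paths
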