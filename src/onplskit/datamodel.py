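"""Core data containers and tabular I/O.

The package works on small multiblock designs: a handful of biological
samples (rows) profiled on several platforms, each platform contributing one
samples x variables matrix (a block).  One :class:`SampleDesign` owns the
sample order and genotype labelling, including which genotype is the
reference (typically wild type); every block is re-ordered to it so that the
sample axis is shared across blocks.

Missing values are first-class: they are carried as NaN inside float
matrices and written back out as a configurable token, never conflated
with 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("onplskit")

#: processing states in pipeline order; later states may only follow earlier ones
STATES = ("raw", "log2", "combined", "centered", "wt_scaled")


def state_rank(state: str) -> int:
    if state not in STATES:
        raise ValueError(f"unknown processing state {state!r}; expected one of {STATES}")
    return STATES.index(state)


# ---------------------------------------------------------------------------
# SampleDesign
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleDesign:
    """Ordered samples with genotype labels and a reference genotype.

    Parameters
    ----------
    sample_ids
        Ordered, unique sample identifiers; this order is canonical for all
        blocks of a dataset.
    genotype_of
        Mapping sample_id -> genotype label; every sample must be labelled.
    reference_genotype
        The genotype whose samples provide the reference mean/sd for
        WT-reference scaling.  Needs at least two samples (a standard
        deviation must be computable).
    replicate_index
        Mapping sample_id -> positive integer biological replicate number.
    """

    sample_ids: tuple[str, ...]
    genotype_of: Mapping[str, str]
    reference_genotype: str
    replicate_index: Mapping[str, int]

    def __post_init__(self) -> None:
        ids = self.sample_ids
        if len(ids) != len(set(ids)):
            dup = sorted({s for s in ids if list(ids).count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dup}")
        missing = [s for s in ids if s not in self.genotype_of]
        if missing:
            raise ValueError(f"samples without genotype label: {missing}")
        genotypes = {self.genotype_of[s] for s in ids}
        if len(genotypes) < 2:
            raise ValueError("a design needs at least 2 distinct genotypes")
        n_ref = len(self.reference_samples)
        if n_ref == 0:
            raise ValueError(
                f"reference genotype {self.reference_genotype!r} absent from design"
            )
        if n_ref < 2:
            raise ValueError(
                f"reference genotype {self.reference_genotype!r} has {n_ref} sample; "
                "at least 2 are required to compute a reference standard deviation"
            )
        for s in ids:
            r = self.replicate_index.get(s)
            if r is None or int(r) < 1:
                raise ValueError(f"sample {s!r} needs a positive replicate index")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def genotypes(self) -> tuple[str, ...]:
        """Genotype labels in first-appearance order."""
        seen: list[str] = []
        for s in self.sample_ids:
            g = self.genotype_of[s]
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    @property
    def non_reference_genotypes(self) -> tuple[str, ...]:
        return tuple(g for g in self.genotypes if g != self.reference_genotype)

    def samples_of(self, genotype: str) -> tuple[str, ...]:
        return tuple(s for s in self.sample_ids if self.genotype_of[s] == genotype)

    @property
    def reference_samples(self) -> tuple[str, ...]:
        return self.samples_of(self.reference_genotype)

    def without(self, sample_id: str) -> "SampleDesign":
        """Leave-one-out design (for jack-knife resampling)."""
        if sample_id not in self.sample_ids:
            raise KeyError(f"sample {sample_id!r} not in design")
        keep = tuple(s for s in self.sample_ids if s != sample_id)
        return SampleDesign(
            sample_ids=keep,
            genotype_of={s: self.genotype_of[s] for s in keep},
            reference_genotype=self.reference_genotype,
            replicate_index={s: self.replicate_index[s] for s in keep},
        )


# ---------------------------------------------------------------------------
# OmicsBlock / MultiBlockDataset
# ---------------------------------------------------------------------------


@dataclass
class OmicsBlock:
    """One platform's samples x variables matrix.

    ``data`` is a float DataFrame whose index holds sample (or technical
    replicate) labels and whose columns hold the variable ids.  NaN marks
    MISSING.  ``state`` tags how far through preprocessing the block is.
    """

    name: str
    data: pd.DataFrame
    platform: str = ""
    state: str = "raw"

    def __post_init__(self) -> None:
        state_rank(self.state)
        if not self.name:
            raise ValueError("block needs a non-empty name")
        cols = list(self.data.columns)
        if len(cols) != len(set(cols)):
            dup = sorted({c for c in cols if cols.count(c) > 1})
            raise ValueError(f"block {self.name!r}: duplicate variable ids {dup}")
        rows = list(self.data.index)
        if len(rows) != len(set(rows)):
            dup = sorted({r for r in rows if rows.count(r) > 1})
            raise ValueError(f"block {self.name!r}: duplicate row labels {dup}")
        self.data = self.data.astype(float)
        all_missing = self.data.columns[self.data.isna().all(axis=0)]
        if len(all_missing):
            raise ValueError(
                f"block {self.name!r}: variables entirely missing: "
                f"{list(all_missing[:5])}"
            )

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def variable_ids(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: pd.DataFrame, state: str | None = None) -> "OmicsBlock":
        return OmicsBlock(
            name=self.name,
            data=data,
            platform=self.platform,
            state=self.state if state is None else state,
        )


@dataclass
class MultiBlockDataset:
    """Two or more blocks co-aligned on one :class:`SampleDesign`."""

    design: SampleDesign
    blocks: list[OmicsBlock]

    def __post_init__(self) -> None:
        if len(self.blocks) < 2:
            raise ValueError("a multiblock dataset needs at least 2 blocks")
        names = [b.name for b in self.blocks]
        if len(names) != len(set(names)):
            raise ValueError(f"block names must be unique, got {names}")
        for b in self.blocks:
            if tuple(b.data.index) != self.design.sample_ids:
                raise ValueError(
                    f"block {b.name!r} rows do not follow the design's sample order; "
                    "use align_blocks() first"
                )

    @property
    def block_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.blocks)

    def block(self, name: str) -> OmicsBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(f"no block named {name!r}")


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def read_block_tsv(
    path: str | Path,
    *,
    orientation: str = "samples_in_rows",
    missing_token: str = "NA",
    name: str | None = None,
    platform: str = "",
) -> OmicsBlock:
    """Read a tab-separated numeric matrix into an :class:`OmicsBlock`.

    The file must have one header row and a leading id column.  With
    ``orientation="variables_in_rows"`` the matrix is transposed so the
    returned block is always samples x variables.  Cells equal to
    ``missing_token`` become MISSING (NaN); any other non-numeric cell is a
    parse error naming its row and column.
    """
    if orientation not in ("samples_in_rows", "variables_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)

    def _check_dup(labels: Sequence[str], axis: str) -> None:
        labels = list(labels)
        if len(labels) != len(set(labels)):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"{path.name}: duplicate {axis} ids {dup}")

    _check_dup(raw.index, "row")
    _check_dup(raw.columns, "column")

    # cell-wise float() keeps the parse correctly rounded (bit-exact round
    # trips) and lets errors name the offending cell
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col]):
            cell = cell.strip()
            if cell == missing_token:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path.name}: non-numeric cell {cell!r} at row "
                    f"{raw.index[i]!r}, column {col!r}"
                ) from None
    numeric = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    if orientation == "variables_in_rows":
        numeric = numeric.T
    numeric.index.name = None
    numeric.columns.name = None
    return OmicsBlock(name=name or path.stem.split(".")[0], data=numeric, platform=platform)


def write_block_tsv(block: OmicsBlock, path: str | Path, *, missing_token: str = "NA") -> None:
    """Write a block as TSV; finite values round-trip bit-exactly."""
    df = block.data.copy()
    df.index.name = "id"
    # str(float) round-trips exactly in Python 3; NaN -> missing token
    df.to_csv(path, sep="\t", na_rep=missing_token)


def read_design_tsv(path: str | Path, reference_genotype: str) -> SampleDesign:
    """Read a sample design table with columns sample_id, genotype, replicate."""
    path = Path(path)
    tbl = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "genotype", "replicate"}
    if not required.issubset(tbl.columns):
        raise ValueError(
            f"{path.name}: design table needs columns {sorted(required)}, "
            f"got {list(tbl.columns)}"
        )
    ids = tuple(tbl["sample_id"])
    return SampleDesign(
        sample_ids=ids,
        genotype_of=dict(zip(tbl["sample_id"], tbl["genotype"])),
        reference_genotype=reference_genotype,
        replicate_index={s: int(r) for s, r in zip(tbl["sample_id"], tbl["replicate"])},
    )


def write_design_tsv(design: SampleDesign, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": design.sample_ids,
            "genotype": [design.genotype_of[s] for s in design.sample_ids],
            "replicate": [design.replicate_index[s] for s in design.sample_ids],
        }
    ).to_csv(path, sep="\t", index=False)


def align_blocks(
    blocks: Sequence[OmicsBlock],
    design: SampleDesign,
    *,
    drop_extra: bool = False,
) -> MultiBlockDataset:
    """Re-order every block's rows to the design order and bundle them.

    Each block's row labels must cover the design's samples.  Extra rows are
    an error unless ``drop_extra`` is set.  Aligning an already aligned
    dataset is a no-op.
    """
    aligned = []
    for b in blocks:
        rows = set(b.data.index)
        missing = [s for s in design.sample_ids if s not in rows]
        if missing:
            raise ValueError(f"block {b.name!r} is missing design sample(s) {missing}")
        extra = sorted(rows - set(design.sample_ids))
        if extra and not drop_extra:
            raise ValueError(
                f"block {b.name!r} has samples not in the design {extra}; "
                "pass drop_extra=True to discard them"
            )
        aligned.append(b.with_data(b.data.loc[list(design.sample_ids)]))
    return MultiBlockDataset(design=design, blocks=aligned)


# ---------------------------------------------------------------------------
# RunConfig
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Flat run configuration mirrored one-to-one in a YAML file."""

    # model
    n_global: int = 2
    filter_orthogonal: bool = True
    ortho_var_ratio: float = 0.05
    tol: float = 1e-9
    max_iter: int = 500
    auto_var_ratio: float = 0.05
    n_local: dict = field(default_factory=dict)  # "blockA,blockB" -> count
    n_unique: dict = field(default_factory=dict)  # block -> count or "auto"
    # preprocessing
    censor_threshold: float = 7.0
    log_offset: float = 0.0
    min_reference_sd: float = 1e-12
    log2_blocks: list = field(default_factory=list)  # blocks that get log2+censor
    # selection
    vip_threshold: float = 0.5
    # plumbing
    seed: int = 0
    output_dir: str = "results"
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("ortho_var_ratio", "tol", "auto_var_ratio", "censor_threshold",
                     "log_offset", "min_reference_sd", "vip_threshold"):
            if not np.isfinite(float(getattr(self, name))):
                raise ValueError(f"RunConfig.{name} must be finite")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        payload = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
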