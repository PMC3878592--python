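"""Matrix-level preprocessing.

The transcript path is: log2 transform, censor low intensities, combine
dye-swap technical replicates (ignoring missing values), mean-center each
array (row), then scale every variable by the reference-genotype (wild-type)
mean and standard deviation.  Protein and metabolite blocks, whose upstream
quantification is assumed done, receive only the WT-reference scaling.

WT-reference scaling puts the wild type at the origin of every platform, so
genotype effects are expressed in units of wild-type standard deviations and
become comparable across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import OmicsBlock, SampleDesign, state_rank

logger = logging.getLogger("onplskit")


@dataclass(frozen=True)
class PreprocessParams:
    """Thresholds for the preprocessing chain.

    censor_threshold
        Log2-scale intensity floor; values below it are raised to it.
    log_offset
        Constant added before log2 (0 keeps the transform exact on
        positive data).
    min_reference_sd
        Variables whose reference sd falls below this are dropped as
        degenerate rather than divided by ~0.
    """

    censor_threshold: float = 7.0
    log_offset: float = 0.0
    min_reference_sd: float = 1e-12

    def __post_init__(self) -> None:
        if not np.isfinite(self.censor_threshold):
            raise ValueError("censor_threshold must be finite")
        if self.log_offset < 0:
            raise ValueError("log_offset must be >= 0")
        if self.min_reference_sd <= 0:
            raise ValueError("min_reference_sd must be positive")


def log2_transform(block: OmicsBlock, params: PreprocessParams = PreprocessParams()) -> OmicsBlock:
    """Entrywise x -> log2(x + log_offset); MISSING passes through."""
    if block.state != "raw":
        raise ValueError(f"log2_transform expects a raw block, got state {block.state!r}")
    shifted = block.data + params.log_offset
    bad = (shifted <= 0) & block.data.notna()
    if bad.to_numpy().any():
        cells = [
            (str(r), str(c))
            for r, c in zip(*np.nonzero(bad.to_numpy()))
        ]
        named = [(block.data.index[i], block.data.columns[j]) for i, j in np.argwhere(bad.to_numpy())[:5]]
        raise ValueError(
            f"block {block.name!r}: nonpositive entries cannot be log2-transformed "
            f"with log_offset={params.log_offset}: first offenders {named}"
        )
    return block.with_data(np.log2(shifted), state="log2")


def censor_low(block: OmicsBlock, params: PreprocessParams = PreprocessParams()) -> OmicsBlock:
    """Raise log2 values below the censoring threshold to the threshold."""
    if state_rank(block.state) < state_rank("log2"):
        raise ValueError("censor_low expects a log2-scale block")
    return block.with_data(block.data.clip(lower=params.censor_threshold))


def combine_dye_swap(
    block: OmicsBlock,
    replicate_map: Mapping[str, Sequence[str]],
) -> OmicsBlock:
    """Average technical replicate rows into one row per biological sample.

    ``replicate_map`` maps each output sample id to the row labels of its
    technical replicates (e.g. the two dye-swap arrays).  Per variable the
    output is the arithmetic mean of the non-missing replicate values; a
    variable missing in every replicate stays MISSING.
    """
    rows = {}
    for sample_id, rep_labels in replicate_map.items():
        rep_labels = list(rep_labels)
        if not rep_labels:
            raise ValueError(f"sample {sample_id!r}: empty replicate set")
        absent = [r for r in rep_labels if r not in block.data.index]
        if absent:
            raise ValueError(
                f"sample {sample_id!r}: replicate label(s) {absent} not in block "
                f"{block.name!r}"
            )
        sub = block.data.loc[rep_labels]
        rows[sample_id] = sub.mean(axis=0, skipna=True)  # all-NaN mean -> NaN
    out = pd.DataFrame(rows).T
    out = out.loc[list(replicate_map)]
    out.columns = block.data.columns
    return block.with_data(out, state="combined")


def center_per_sample(block: OmicsBlock) -> OmicsBlock:
    """Subtract each row's mean over its observed entries."""
    observed = block.data.notna()
    if not observed.any(axis=1).all():
        empty = list(block.data.index[~observed.any(axis=1)])
        raise ValueError(f"block {block.name!r}: rows entirely missing: {empty}")
    centered = block.data.sub(block.data.mean(axis=1, skipna=True), axis=0)
    return block.with_data(centered, state="centered")


def wt_reference_scale(
    block: OmicsBlock,
    design: SampleDesign,
    params: PreprocessParams = PreprocessParams(),
) -> OmicsBlock:
    """Standardize every variable by the reference-genotype mean and sd.

    For variable j, all samples (reference included) are transformed as
    ``z = (x - mean_ref_j) / sd_ref_j`` with the sd computed over the
    reference samples with the n-1 denominator.  Variables with fewer than
    two observed reference values, or reference sd below
    ``params.min_reference_sd``, are dropped with a warning.
    """
    if tuple(block.data.index) != design.sample_ids:
        raise ValueError(
            f"block {block.name!r} rows must follow the design order before scaling"
        )
    ref = block.data.loc[list(design.reference_samples)]
    n_obs = ref.notna().sum(axis=0)
    mean_ref = ref.mean(axis=0, skipna=True)
    sd_ref = ref.std(axis=0, ddof=1, skipna=True)

    too_few = n_obs < 2
    degenerate = (~too_few) & (sd_ref < params.min_reference_sd)
    drop = block.data.columns[too_few | degenerate]
    if len(drop):
        logger.warning(
            "block %r: dropping %d variable(s) during WT-reference scaling "
            "(%d with <2 observed reference values, %d with reference sd < %g): %s",
            block.name,
            len(drop),
            int(too_few.sum()),
            int(degenerate.sum()),
            params.min_reference_sd,
            list(drop[:10]),
        )
    keep = [c for c in block.data.columns if c not in set(drop)]
    if not keep:
        raise ValueError(f"block {block.name!r}: no variables survive WT-reference scaling")
    scaled = (block.data[keep] - mean_ref[keep]) / sd_ref[keep]
    return block.with_data(scaled, state="wt_scaled")


def impute_missing(block: OmicsBlock, strategy: str = "variable_mean") -> OmicsBlock:
    """Remove MISSING entries so the decomposition sees complete matrices.

    ``variable_mean`` replaces each missing cell with its variable's mean
    over observed samples (all-missing variables are dropped with a
    warning); ``drop_variable`` removes every variable with any missing
    entry.
    """
    if strategy not in ("variable_mean", "drop_variable"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    data = block.data
    if not data.isna().to_numpy().any():
        return block.with_data(data.copy())
    if strategy == "drop_variable":
        keep = data.columns[data.notna().all(axis=0)]
        dropped = [c for c in data.columns if c not in set(keep)]
        logger.info("block %r: dropping %d incomplete variable(s): %s",
                    block.name, len(dropped), dropped[:10])
        return block.with_data(data[list(keep)].copy())
    n_imputed = int(data.isna().to_numpy().sum())
    filled = data.fillna(data.mean(axis=0, skipna=True))
    logger.info("block %r: imputed %d missing cell(s) with variable means",
                block.name, n_imputed)
    return block.with_data(filled)


def preprocess_block(
    block: OmicsBlock,
    design: SampleDesign,
    params: PreprocessParams = PreprocessParams(),
    *,
    apply_log2: bool = False,
    replicate_map: Mapping[str, Sequence[str]] | None = None,
    center_before_combine: bool = False,
) -> OmicsBlock:
    """Run the per-block preprocessing chain through WT-reference scaling.

    Transcript-style blocks (``apply_log2=True``) get log2 + censoring;
    blocks with a ``replicate_map`` get their technical replicates combined
    (by default before per-sample centering).  Every block ends with
    imputation of remaining MISSING entries and WT-reference scaling.
    """
    b = block
    if apply_log2:
        b = censor_low(log2_transform(b, params), params)
        if replicate_map is not None:
            if center_before_combine:
                b = combine_dye_swap(center_per_sample(b), replicate_map)
            else:
                b = center_per_sample(combine_dye_swap(b, replicate_map))
        else:
            b = center_per_sample(b)
    elif replicate_map is not None:
        b = combine_dye_swap(b, replicate_map)
    b = impute_missing(b)
    return wt_reference_scale(b, design, params)
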