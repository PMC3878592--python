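"""Variable selection: VIP, jack-knife confidence intervals, significance
calls and per-line direction arrows.

A variable is called significant when its VIP over the globally joint
components exceeds the threshold (strictly; default 0.5) *and* the
jack-knife 95% confidence interval of its dominant global loading excludes
zero.  Directions (up / down / unchanged) are the sign of the variable's
mean WT-scaled value within each non-reference line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MultiBlockDataset, OmicsBlock, SampleDesign
from .onpls import ModelSpec, OnPLSModel, fit_frames
from .preprocessing import PreprocessParams, wt_reference_scale

logger = logging.getLogger("onplskit")


@dataclass
class VIPResult:
    """Per-variable importance for one block's globally joint structure."""

    block: str
    vip: pd.Series  # indexed by variable id
    weights: np.ndarray  # N x n_global unit-norm weight columns
    variance_shares: np.ndarray  # SS_a = ||t_a p_a^T||_F^2 per global component


@dataclass
class JackknifeResult:
    """Leave-one-sample-out uncertainty of one block's dominant loadings.

    ``table`` columns: theta (full-model loading on the variable's dominant
    global component), se, ci_low, ci_high, dominant_component.
    """

    block: str
    table: pd.DataFrame
    n_resamples: int


@dataclass
class SignificanceTable:
    """Per-variable selection results for one block.

    ``table`` columns: vip, theta, ci_low, ci_high, significant, and, once
    :func:`direction_arrows` has run, dir_<line> in {+1, -1, 0} and
    mean_<line> (mean WT-scaled value of the line's samples).
    """

    block: str
    table: pd.DataFrame

    @property
    def lines(self) -> tuple[str, ...]:
        return tuple(c[len("dir_"):] for c in self.table.columns if c.startswith("dir_"))

    def significant_ids(self) -> tuple[str, ...]:
        return tuple(self.table.index[self.table["significant"]])


def jackknife_se(values) -> float:
    """Jack-knife standard error of a vector of leave-one-out statistics:
    ``sqrt((M-1)/M * sum_m (theta_m - mean)^2)``."""
    v = np.asarray(values, dtype=float)
    m = len(v)
    if m < 2:
        raise ValueError("need at least 2 leave-one-out values")
    return float(np.sqrt((m - 1) / m * ((v - v.mean()) ** 2).sum()))


def compute_vip(model: OnPLSModel, block_name: str) -> VIPResult:
    """Variable importance in projection over the block's global components.

    ``VIP_k = sqrt(N * sum_a SS_a w_ak^2 / sum_a SS_a)`` with ``SS_a`` the
    variance captured by global component ``a`` of this block and ``w_a``
    its unit-norm weight.  The mean of VIP^2 over variables is exactly 1.
    """
    comps = sorted(
        (c for c in model.components[block_name] if c.kind == "global"),
        key=lambda c: c.index,
    )
    if not comps:
        raise ValueError(f"block {block_name!r}: model has no global components")
    W = np.column_stack([c.w for c in comps])
    SS = np.array([c.variance for c in comps])
    if not SS.sum() > 0:
        raise ValueError(f"block {block_name!r}: no joint variance (all SS_a = 0)")
    N = W.shape[0]
    vip = np.sqrt(N * (W ** 2) @ SS / SS.sum())
    return VIPResult(
        block=block_name,
        vip=pd.Series(vip, index=list(model.variable_ids[block_name]), name="vip"),
        weights=W,
        variance_shares=SS,
    )


def _dominant_components(model: OnPLSModel, block: str) -> pd.Series:
    P = model.global_loadings(block)
    dom = np.argmax(np.abs(P), axis=1)
    return pd.Series(dom, index=list(model.variable_ids[block]))


def _scale_frames(
    dataset: MultiBlockDataset,
    design: SampleDesign,
    params: PreprocessParams,
) -> dict[str, pd.DataFrame]:
    out = {}
    for b in dataset.blocks:
        sub = b.with_data(b.data.loc[list(design.sample_ids)])
        out[b.name] = wt_reference_scale(sub, design, params).data
    return out


def jackknife(
    dataset: MultiBlockDataset,
    spec: ModelSpec | None = None,
    params: PreprocessParams = PreprocessParams(),
    *,
    rescale: bool = False,
    statistic: str = "loading",
) -> dict[str, JackknifeResult]:
    """Leave-one-sample-out confidence intervals for the dominant loadings.

    By default each resample drops one biological sample from the (already
    preprocessed) blocks and refits -- the standard PLS jackknife.  With
    ``rescale=True`` the dataset must hold blocks *before* WT-reference
    scaling; each resample then also recomputes the reference scaling on
    the remaining reference samples (falling back to the full-model
    statistics when fewer than two remain, with a log message), which
    propagates scaling uncertainty but is fragile with very few reference
    samples.  Resampled global components are aligned to the full model by
    orthogonal Procrustes rotation of their loadings (pure sign alignment
    in the one-component case).  Per variable, with M resamples,

        var = (M-1)/M * sum_m (theta_(-m) - mean)^2,
        CI  = theta_full +- t_{0.975, M-1} * sqrt(var).

    ``statistic="vip"`` jack-knifes the VIP value instead of the dominant
    loading.  Returns one :class:`JackknifeResult` per block.
    """
    if statistic not in ("loading", "vip"):
        raise ValueError(f"unknown jackknife statistic {statistic!r}")
    spec = spec or ModelSpec()
    design = dataset.design
    M = design.n_samples
    if M < 3:
        raise ValueError("jackknife needs at least 3 samples")

    if rescale:
        full_frames = _scale_frames(dataset, design, params)
    else:
        full_frames = {b.name: b.data for b in dataset.blocks}
    full_model = fit_frames(full_frames, design.sample_ids, spec)
    names = sorted(full_frames)
    dom = {n: _dominant_components(full_model, n) for n in names}

    def statistic_of(model: OnPLSModel, block: str) -> pd.Series:
        if statistic == "vip":
            return compute_vip(model, block).vip
        P = pd.DataFrame(
            model.global_loadings(block), index=list(model.variable_ids[block])
        )
        d = dom[block].reindex(P.index)
        vals = [
            P.at[v, int(d[v])] if pd.notna(d[v]) else np.nan for v in P.index
        ]
        return pd.Series(vals, index=P.index, name="theta")

    theta_full = {n: statistic_of(full_model, n) for n in names}
    resample_thetas: dict[str, list[pd.Series]] = {n: [] for n in names}

    for left_out in design.sample_ids:
        keep = [s for s in design.sample_ids if s != left_out]
        try:
            sub_design = design.without(left_out)
            frames = (
                _scale_frames(dataset, sub_design, params)
                if rescale
                else {n: full_frames[n].loc[keep] for n in names}
            )
        except ValueError:
            logger.info(
                "jackknife: removing %r leaves <2 reference samples; using "
                "full-model reference statistics for this resample", left_out)
            frames = {n: full_frames[n].loc[keep] for n in names}
        sub_model = fit_frames(frames, tuple(keep), spec)
        # Align each resample's global components to the full model by
        # orthogonal Procrustes rotation of the loading matrix.  Leaving a
        # sample out can rotate the extracted components within the joint
        # subspace (not merely flip signs); comparing unaligned loadings
        # would inflate the jackknife variance with rotation noise.  With a
        # single component, or no rotation, this reduces to sign alignment.
        for n in names:
            if statistic == "vip":
                resample_thetas[n].append(
                    statistic_of(sub_model, n).reindex(theta_full[n].index)
                )
                continue
            P_full = pd.DataFrame(
                full_model.global_loadings(n), index=list(full_model.variable_ids[n])
            )
            P_sub = pd.DataFrame(
                sub_model.global_loadings(n), index=list(sub_model.variable_ids[n])
            )
            shared = P_full.index.intersection(P_sub.index)
            U, _s, Vt = np.linalg.svd(
                P_sub.loc[shared].to_numpy().T @ P_full.loc[shared].to_numpy()
            )
            Q = U @ Vt
            P_rot = pd.DataFrame(P_sub.to_numpy() @ Q, index=P_sub.index)
            d = dom[n].reindex(theta_full[n].index)
            vals = [
                P_rot.at[v, int(d[v])] if v in P_rot.index else np.nan
                for v in theta_full[n].index
            ]
            resample_thetas[n].append(
                pd.Series(vals, index=theta_full[n].index, name="theta")
            )

    results = {}
    t_crit = float(stats.t.ppf(0.975, M - 1))
    for n in names:
        theta = pd.concat(resample_thetas[n], axis=1)  # variables x M
        n_eff = theta.notna().sum(axis=1)
        mean = theta.mean(axis=1, skipna=True)
        var = (n_eff - 1) / n_eff * ((theta.sub(mean, axis=0)) ** 2).sum(axis=1, skipna=True)
        se = np.sqrt(var)
        tab = pd.DataFrame(
            {
                "theta": theta_full[n],
                "se": se,
                "ci_low": theta_full[n] - t_crit * se,
                "ci_high": theta_full[n] + t_crit * se,
                "dominant_component": dom[n].reindex(theta_full[n].index),
            }
        )
        results[n] = JackknifeResult(block=n, table=tab, n_resamples=M)
    return results


def call_significance(
    vip: VIPResult,
    jk: JackknifeResult,
    threshold: float = 0.5,
) -> SignificanceTable:
    """Two-gate significance call: VIP strictly above threshold and
    jack-knife CI excluding zero."""
    if vip.block != jk.block:
        raise ValueError(f"block mismatch: VIP for {vip.block!r}, jackknife for {jk.block!r}")
    if set(vip.vip.index) != set(jk.table.index):
        raise ValueError("VIP and jackknife tables cover different variables")
    tab = jk.table.loc[vip.vip.index].copy()
    tab.insert(0, "vip", vip.vip)
    ci_excludes_zero = (tab["ci_low"] > 0) | (tab["ci_high"] < 0)
    tab["significant"] = (tab["vip"] > threshold) & ci_excludes_zero
    return SignificanceTable(block=vip.block, table=tab)


def direction_arrows(
    block_wt_scaled: OmicsBlock,
    design: SampleDesign,
    table: SignificanceTable,
) -> SignificanceTable:
    """Attach per-line directions: sign of the line's mean WT-scaled value.

    Significant variables get +1 (up) or -1 (down); non-significant rows
    get 0; an exactly-zero mean yields 0 with a warning.
    """
    if block_wt_scaled.state != "wt_scaled":
        raise ValueError("direction_arrows needs a wt_scaled block")
    tab = table.table.copy()
    for line in design.non_reference_genotypes:
        samples = list(design.samples_of(line))
        if not samples:
            raise ValueError(f"genotype {line!r} has no samples")
        means = block_wt_scaled.data.loc[samples].mean(axis=0).reindex(tab.index)
        if means.isna().any():
            logger.warning(
                "block %r: %d variable(s) absent from the scaled block; "
                "their direction is set to 0", table.block, int(means.isna().sum()))
        direction = np.sign(means).fillna(0).astype(int)
        zero_sig = tab["significant"] & (direction == 0)
        if zero_sig.any():
            logger.warning(
                "block %r: %d significant variable(s) with exactly zero mean in "
                "line %r; direction set to 0", table.block, int(zero_sig.sum()), line)
        tab[f"mean_{line}"] = means
        tab[f"dir_{line}"] = direction.where(tab["significant"], 0)
    return SignificanceTable(block=table.block, table=tab)


def coregulation_fraction(
    protein_table: SignificanceTable,
    transcript_table: SignificanceTable,
    mapping: Mapping[str, str],
) -> float:
    """Fraction of (significant protein, line) pairs whose mapped transcript
    is significant with the same direction in that line."""
    prot = protein_table.table
    trans = transcript_table.table
    if prot.empty:
        raise ValueError("empty protein significance table")
    unmapped = [p for p in prot.index[prot["significant"]] if p not in mapping]
    if unmapped:
        raise ValueError(f"significant protein(s) without transcript mapping: {unmapped[:5]}")
    lines = protein_table.lines
    if not lines:
        raise ValueError("run direction_arrows before computing coregulation")
    total = 0
    concordant = 0
    for p in prot.index[prot["significant"]]:
        t = mapping[p]
        for line in lines:
            total += 1
            if t not in trans.index or not bool(trans.at[t, "significant"]):
                continue
            dp = int(prot.at[p, f"dir_{line}"])
            dt = int(trans.at[t, f"dir_{line}"])
            if dp != 0 and dp == dt:
                concordant += 1
    if total == 0:
        raise ValueError("no significant proteins; coregulation undefined")
    return concordant / total


def select_block(
    model: OnPLSModel,
    jk: dict[str, JackknifeResult],
    block_wt_scaled: OmicsBlock,
    design: SampleDesign,
    threshold: float = 0.5,
) -> SignificanceTable:
    """Convenience chain: VIP -> significance gates -> direction arrows."""
    vip = compute_vip(model, block_wt_scaled.name)
    table = call_significance(vip, jk[block_wt_scaled.name], threshold)
    return direction_arrows(block_wt_scaled, design, table)
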