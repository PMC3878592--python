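"""Multiblock joint/unique variance decomposition (OnPLS; O2PLS as the
two-block case).

Each preprocessed block ``X_i`` (samples x variables) is split additively as

    X_i = sum_a t_a p_a^T + E_i

where the rank-one components are classified as *globally joint* (a score
shared by all blocks), *locally joint* (shared by a proper subset of
blocks) or *unique* (block-specific), and ``E_i`` is the residual.  The
method is symmetric: no block is treated as predictor or response, and the
result does not depend on the order in which blocks are supplied.

Algorithm
---------
Joint components are consensus directions maximizing the sum of pairwise
score covariances

    J = sum_{i<j} (X_i w_i)^T (X_j w_j),   ||w_i|| = 1,

found by cyclic alternating least squares (each update is the exact
maximizer for one block given the others, so J is non-decreasing).  For two
blocks this reduces to the leading singular pair of ``X_1^T X_2``.
Orthogonal (unique) variation that would otherwise distort the joint
directions is filtered O2PLS-style: after each consensus fit, per-block
candidates ``w_o = p - (w^T p) w`` are extracted and deflated when they
carry enough variance, and the consensus is re-run.  Extraction is staged
global -> local (by decreasing subset size, data-driven order within a
size) -> unique (principal components of the residual), with each accepted
component deflated (``X <- X - t p^T``), which makes successive scores
orthogonal within a block and the variance decomposition exactly additive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .datamodel import MultiBlockDataset, SampleDesign

logger = logging.getLogger("onplskit")

_ZERO_VARIANCE_REL = 1e-12  # residual energy below this fraction counts as exhausted


class NoVariationError(ValueError):
    """Raised when a block offers no extractable variation."""


# ---------------------------------------------------------------------------
# Specs and result containers
# ---------------------------------------------------------------------------


def _canon_subset(subset: Iterable[str]) -> tuple[str, ...]:
    return tuple(sorted(subset))


@dataclass
class ModelSpec:
    """Component counts and numerical controls for a fit.

    ``n_local`` maps a subset of block names (any iterable; canonicalized to
    a sorted tuple) to a count or ``"auto"``; ``n_unique`` maps block name
    to a count or ``"auto"``, or is a single value applied to all blocks.
    Under ``"auto"`` components are accepted while each captures at least
    ``auto_var_ratio`` of the block's original squared Frobenius norm.
    """

    n_global: int = 2
    n_local: Mapping = field(default_factory=dict)
    n_unique: Mapping | int | str = 0
    filter_orthogonal: bool = True
    ortho_var_ratio: float = 0.05
    tol: float = 1e-9
    max_iter: int = 500
    auto_var_ratio: float = 0.05

    def __post_init__(self) -> None:
        if self.n_global < 1:
            raise ValueError("n_global must be >= 1")
        if not (0 < self.ortho_var_ratio < 1):
            raise ValueError("ortho_var_ratio must be in (0, 1)")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")
        self.n_local = {_canon_subset(k): v for k, v in dict(self.n_local).items()}

    def local_count(self, subset: tuple[str, ...]):
        return self.n_local.get(_canon_subset(subset), 0)

    def unique_count(self, block: str):
        if isinstance(self.n_unique, (int, str)):
            return self.n_unique
        return dict(self.n_unique).get(block, 0)

    def validate_rank_bounds(self, block_names: Sequence[str], n_samples: int) -> None:
        for name in block_names:
            n_loc = sum(
                v
                for s, v in self.n_local.items()
                if name in s and isinstance(v, int)
            )
            n_uni = self.unique_count(name)
            n_uni = n_uni if isinstance(n_uni, int) else 0
            total = self.n_global + n_loc + n_uni
            if total > n_samples - 1:
                raise ValueError(
                    f"block {name!r}: requested {total} components exceeds the "
                    f"rank bound M-1 = {n_samples - 1}"
                )


@dataclass
class Component:
    """One rank-one component of one block."""

    block: str
    kind: str  # "global" | "local" | "unique"
    index: int  # consensus index for global; per-kind counter otherwise
    w: np.ndarray  # unit-norm weight (variables)
    t: np.ndarray  # score (samples)
    p: np.ndarray  # loading (variables), p = X^T t / (t^T t) on the residual
    subset: tuple[str, ...] | None = None  # block names for local components

    @property
    def variance(self) -> float:
        """Squared Frobenius norm of t p^T."""
        return float(self.t @ self.t) * float(self.p @ self.p)


@dataclass
class R2Table:
    """Per-block variance fractions of the preprocessed input."""

    table: dict  # block -> {"global": x, "local": {subset: x}, "unique": x, "residual": x}

    def row(self, block: str) -> dict:
        return self.table[block]

    def parts_sum(self, block: str) -> float:
        row = self.table[block]
        return row["global"] + sum(row["local"].values()) + row["unique"] + row["residual"]

    def as_frame(self) -> pd.DataFrame:
        blocks = sorted(self.table)
        subsets = sorted({s for b in blocks for s in self.table[b]["local"]})
        records = {}
        for b in blocks:
            row = {"global": self.table[b]["global"]}
            for s in subsets:
                row[f"local:{'+'.join(s)}"] = self.table[b]["local"].get(s, 0.0)
            row["unique"] = self.table[b]["unique"]
            row["residual"] = self.table[b]["residual"]
            records[b] = row
        out = pd.DataFrame(records).T
        out.index.name = "block"
        return out


@dataclass
class OnPLSModel:
    """Fitted decomposition: per-block components, residuals, R2 ledger."""

    spec: ModelSpec
    block_names: tuple[str, ...]
    sample_ids: tuple[str, ...]
    variable_ids: dict  # block -> tuple of ids
    components: dict  # block -> list[Component] in extraction order
    residuals: dict  # block -> ndarray
    input_sq_norms: dict  # block -> ||X||_F^2 of the preprocessed input
    r2: R2Table
    convergence_log: list = field(default_factory=list)

    def block_components(self, block: str, kind: str | None = None) -> list[Component]:
        comps = self.components[block]
        if kind is None:
            return list(comps)
        return [c for c in comps if c.kind == kind]

    def global_scores(self, block: str) -> np.ndarray:
        """Samples x n_global score matrix of one block (consensus order)."""
        comps = sorted(self.block_components(block, "global"), key=lambda c: c.index)
        return np.column_stack([c.t for c in comps])

    def consensus_global_scores(self) -> np.ndarray:
        """Unweighted mean of the per-block global scores (blocks sorted by name)."""
        names = sorted(self.block_names)
        return np.mean([self.global_scores(b) for b in names], axis=0)

    def global_loadings(self, block: str) -> np.ndarray:
        comps = sorted(self.block_components(block, "global"), key=lambda c: c.index)
        return np.column_stack([c.p for c in comps])


# ---------------------------------------------------------------------------
# Consensus extraction
# ---------------------------------------------------------------------------


def _init_weight(Xi: np.ndarray, others: Sequence[np.ndarray]) -> np.ndarray:
    """Leading left singular vector of [X_i^T X_j]_{j != i}, via the M x M
    sample-space eigenproblem (C C^T = X_i^T (sum_j X_j X_j^T) X_i)."""
    A = np.zeros((Xi.shape[0], Xi.shape[0]))
    for Xj in others:
        A += Xj @ Xj.T
    K = Xi @ Xi.T
    # leading eigenvector z of A K gives w = X_i^T z
    vals, vecs = scipy.linalg.eig(A @ K)
    z = np.real(vecs[:, int(np.argmax(np.real(vals)))])
    w = Xi.T @ z
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise NoVariationError("no extractable variation (zero cross-covariance init)")
    return w / nrm


def extract_consensus_component(
    blocks_residual: Mapping[str, np.ndarray],
    tol: float = 1e-9,
    max_iter: int = 500,
):
    """One consensus (joint) component across >= 2 blocks.

    Maximizes ``J = sum_{i<j} (X_i w_i)^T (X_j w_j)`` over unit-norm
    weights by cyclic alternating updates ``w_i <- normalize(X_i^T sum_{j!=i}
    X_j w_j)``.  Blocks are visited in sorted-name order, so the arithmetic
    is independent of input ordering.

    Returns ``(comps, trajectory, converged)`` where ``comps`` maps block
    name to a dict with keys ``w``, ``t``, ``p`` and ``trajectory`` is the
    per-iteration objective (non-decreasing).
    """
    names = sorted(blocks_residual)
    if len(names) < 2:
        raise ValueError("consensus extraction needs at least 2 blocks")
    X = {n: np.asarray(blocks_residual[n], dtype=float) for n in names}
    for n in names:
        if not np.linalg.norm(X[n]) > 0:
            raise NoVariationError(f"block {n!r}: no extractable variation (zero residual)")

    w = {n: _init_weight(X[n], [X[m] for m in names if m != n]) for n in names}
    t = {n: X[n] @ w[n] for n in names}

    trajectory: list[float] = []
    converged = False
    for _ in range(max_iter):
        delta = 0.0
        for n in names:
            s = np.zeros(next(iter(t.values())).shape)
            for m in names:
                if m != n:
                    s = s + t[m]
            wi = X[n].T @ s
            nrm = np.linalg.norm(wi)
            if nrm == 0:
                raise NoVariationError(
                    f"block {n!r}: weight update collapsed to zero (no joint variation)"
                )
            wi = wi / nrm
            delta = max(delta, float(np.linalg.norm(wi - w[n])))
            w[n] = wi
            t[n] = X[n] @ wi
        J = 0.0
        for i, n in enumerate(names):
            for m in names[i + 1:]:
                J += float(t[n] @ t[m])
        trajectory.append(J)
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "consensus extraction did not converge in %d iterations (last delta %.3g)",
            max_iter, delta,
        )
    scale = 0.0
    for i, n in enumerate(names):
        for m in names[i + 1:]:
            scale += float(np.linalg.norm(X[n]) * np.linalg.norm(X[m]))
    if trajectory[-1] <= 1e-10 * scale:
        logger.warning("consensus objective is negligible (%.3g): blocks share "
                       "little or no joint variation", trajectory[-1])

    # sign convention: largest-|.| weight entry of the first (sorted) block
    # positive; every other block's score positively correlated with it
    ref = names[0]
    if w[ref][int(np.argmax(np.abs(w[ref])))] < 0:
        w[ref] = -w[ref]
        t[ref] = -t[ref]
    for n in names[1:]:
        if float(t[n] @ t[ref]) < 0:
            w[n] = -w[n]
            t[n] = -t[n]

    comps = {}
    for n in names:
        tt = float(t[n] @ t[n])
        if tt == 0:
            raise NoVariationError(f"block {n!r}: zero score in consensus component")
        comps[n] = {"w": w[n], "t": t[n], "p": X[n].T @ t[n] / tt}
    return comps, trajectory, converged


def extract_orthogonal_candidate(
    block_residual: np.ndarray,
    w: np.ndarray,
    p: np.ndarray,
    ortho_var_ratio: float = 0.05,
    extra_weights: Sequence[np.ndarray] = (),
):
    """O2PLS-style within-block orthogonal component, or None.

    The candidate weight is the part of the joint loading not along the
    joint weight, ``w_o = p - (w^T p) w``, additionally orthogonalized
    against any ``extra_weights`` (the other joint components' weights, so
    that globally joint structure is never misclassified as unique).  The
    component is kept only if it captures at least ``ortho_var_ratio`` of
    the matrix's squared Frobenius norm.
    """
    X = np.asarray(block_residual, dtype=float)
    w = np.asarray(w, dtype=float)
    if not np.isclose(np.linalg.norm(w), 1.0, atol=1e-8):
        raise ValueError("joint weight must be unit-norm")
    wo = np.asarray(p, dtype=float) - float(w @ p) * w
    for wk in extra_weights:
        wk = np.asarray(wk, dtype=float)
        wo = wo - float(wk @ wo) * wk
    nrm = np.linalg.norm(wo)
    sq = float(np.sum(X * X))
    # below ~1e-8 of ||p|| the candidate is numerical residue of the ALS
    # iteration (weight tolerance 1e-9), not structure: normalizing it would
    # manufacture an arbitrary direction
    if nrm == 0 or sq == 0 or nrm <= 1e-8 * max(1e-30, np.linalg.norm(p)):
        return None
    wo = wo / nrm
    to = X @ wo
    tt = float(to @ to)
    if tt == 0:
        return None
    po = X.T @ to / tt
    if tt * float(po @ po) / sq < ortho_var_ratio:
        return None
    if wo[int(np.argmax(np.abs(wo)))] < 0:
        wo, to, po = -wo, -to, -po
    return {"w": wo, "t": to, "p": po}


# ---------------------------------------------------------------------------
# Full fit
# ---------------------------------------------------------------------------


def _leading_pc(X: np.ndarray):
    """Leading principal component of a (not re-centered) residual matrix."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    w = Vt[0]
    if w[int(np.argmax(np.abs(w)))] < 0:
        w = -w
    t = X @ w
    tt = float(t @ t)
    if tt == 0:
        return None
    p = X.T @ t / tt
    return {"w": w, "t": t, "p": p}


def fit_onpls(dataset: MultiBlockDataset, spec: ModelSpec | None = None) -> OnPLSModel:
    """Fit the staged global / local / unique decomposition.

    Blocks must be complete (no MISSING); they are expected to be centered
    or WT-reference scaled.  All cross-block arithmetic runs in sorted
    block-name order, so permuting the dataset's block order changes
    nothing in the result.
    """
    frames = {}
    for b in dataset.blocks:
        if b.state == "raw":
            logger.warning("block %r is tagged state='raw'; fitting it as-is "
                           "(expected centered or wt_scaled data)", b.name)
        frames[b.name] = b.data
    return fit_frames(frames, dataset.design.sample_ids, spec,
                      block_order=dataset.block_names)


def fit_frames(
    frames: Mapping[str, pd.DataFrame],
    sample_ids: Sequence[str],
    spec: ModelSpec | None = None,
    *,
    block_order: Sequence[str] | None = None,
) -> OnPLSModel:
    """Array-level fit on named samples x variables frames.

    Exists so resampling schemes (e.g. the jack-knife) can refit reduced
    data without constructing a full dataset; :func:`fit_onpls` is the
    user-facing wrapper.
    """
    spec = spec or ModelSpec()
    names = sorted(frames)
    M = len(sample_ids)
    spec.validate_rank_bounds(names, M)

    X0: dict[str, np.ndarray] = {}
    for name in names:
        df = frames[name]
        if tuple(df.index) != tuple(sample_ids):
            raise ValueError(f"block {name!r} rows do not match the sample ids")
        vals = df.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"block {name!r} contains MISSING values; impute first")
        X0[name] = vals
    sq0 = {n: float(np.sum(X0[n] ** 2)) for n in names}
    for n in names:
        if sq0[n] == 0:
            raise NoVariationError(f"block {n!r} is identically zero")

    R = {n: X0[n].copy() for n in names}
    components: dict[str, list[Component]] = {n: [] for n in names}
    convergence_log: list[dict] = []
    unique_counter = {n: 0 for n in names}

    def record_unique(name: str, comp: dict, origin: str) -> None:
        unique_counter[name] += 1
        components[name].append(
            Component(block=name, kind="unique", index=unique_counter[name] - 1,
                      w=comp["w"], t=comp["t"], p=comp["p"])
        )
        R[name] -= np.outer(comp["t"], comp["p"])
        logger.info("block %r: unique component %d accepted (%s), %.2f%% of input variance",
                    name, unique_counter[name], origin,
                    100 * comp["t"] @ comp["t"] * (comp["p"] @ comp["p"]) / sq0[name])

    # --- Stage A: globally joint components with interleaved orthogonal
    # filtering.  Each round extracts the full provisional set of global
    # components, then looks for within-block variation orthogonal to the
    # whole joint weight matrix; accepted candidates are deflated as unique
    # and the global set is re-extracted, until no candidate passes.
    def _provisional_global():
        Rg = {n: R[n].copy() for n in names}
        cons_list = []
        for a in range(spec.n_global):
            cons, traj, converged = extract_consensus_component(Rg, spec.tol, spec.max_iter)
            convergence_log.append(
                {"stage": "global", "component": a, "subset": tuple(names),
                 "iterations": len(traj), "objective": traj, "converged": converged}
            )
            cons_list.append(cons)
            for n in names:
                Rg[n] -= np.outer(cons[n]["t"], cons[n]["p"])
        return cons_list

    while True:
        cons_list = _provisional_global()
        if not spec.filter_orthogonal:
            break
        accepted = False
        for n in names:
            weights = [cons[n]["w"] for cons in cons_list]
            for a, cons in enumerate(cons_list):
                others = weights[:a] + weights[a + 1:]
                cand = extract_orthogonal_candidate(
                    R[n], cons[n]["w"], cons[n]["p"], spec.ortho_var_ratio,
                    extra_weights=others,
                )
                if cand is not None:
                    record_unique(n, cand, f"orthogonal filter of global {a + 1}")
                    accepted = True
                    break  # one candidate per block per round
        if not accepted:
            break
    for a, cons in enumerate(cons_list):
        for n in names:
            c = cons[n]
            components[n].append(
                Component(block=n, kind="global", index=a, w=c["w"], t=c["t"], p=c["p"])
            )
            R[n] -= np.outer(c["t"], c["p"])

    # --- Stage B: locally joint components, larger subsets first
    all_subsets = [
        _canon_subset(s)
        for size in range(len(names) - 1, 1, -1)
        for s in combinations(names, size)
    ]
    remaining: dict[tuple[str, ...], object] = {}
    for s in all_subsets:
        cnt = spec.local_count(s)
        if cnt == "auto" or (isinstance(cnt, int) and cnt > 0):
            remaining[s] = cnt
    for size in range(len(names) - 1, 1, -1):
        while True:
            candidates = [s for s in remaining if len(s) == size]
            if not candidates:
                break
            trials = {}
            for s in candidates:
                try:
                    trials[s] = extract_consensus_component(
                        {n: R[n] for n in s}, spec.tol, spec.max_iter
                    )
                except NoVariationError:
                    continue
            if not trials:
                break
            best = max(trials, key=lambda s: (trials[s][1][-1], tuple(reversed(s))))
            cons, traj, converged = trials[best]
            if remaining[best] == "auto":
                shares = {
                    n: cons[n]["t"] @ cons[n]["t"] * (cons[n]["p"] @ cons[n]["p"]) / sq0[n]
                    for n in best
                }
                if min(shares.values()) < spec.auto_var_ratio:
                    del remaining[best]
                    continue
            convergence_log.append(
                {"stage": "local", "component": None, "subset": best,
                 "iterations": len(traj), "objective": traj, "converged": converged}
            )
            idx = sum(1 for c in components[best[0]] if c.kind == "local" and c.subset == best)
            for n in best:
                c = cons[n]
                components[n].append(
                    Component(block=n, kind="local", index=idx, w=c["w"], t=c["t"],
                              p=c["p"], subset=best)
                )
                R[n] -= np.outer(c["t"], c["p"])
            if remaining[best] != "auto":
                remaining[best] -= 1
                if remaining[best] == 0:
                    del remaining[best]

    # --- Stage C: unique principal components of each residual
    for n in names:
        want = spec.unique_count(n)
        k = 0
        while True:
            if want == "auto":
                pass
            elif k >= want:
                break
            if float(np.sum(R[n] ** 2)) <= _ZERO_VARIANCE_REL * sq0[n]:
                if want != "auto" and k < want:
                    logger.warning(
                        "block %r: residual exhausted after %d of %d requested "
                        "unique components", n, k, want)
                break
            comp = _leading_pc(R[n])
            if comp is None:
                break
            share = comp["t"] @ comp["t"] * (comp["p"] @ comp["p"]) / sq0[n]
            if want == "auto" and share < spec.auto_var_ratio:
                break
            record_unique(n, comp, "residual PCA")
            k += 1

    # --- R2 ledger
    table = {}
    for n in names:
        row = {"global": 0.0, "local": {}, "unique": 0.0}
        for c in components[n]:
            frac = c.variance / sq0[n]
            if c.kind == "global":
                row["global"] += frac
            elif c.kind == "local":
                row["local"][c.subset] = row["local"].get(c.subset, 0.0) + frac
            else:
                row["unique"] += frac
        row["residual"] = float(np.sum(R[n] ** 2)) / sq0[n]
        table[n] = row

    return OnPLSModel(
        spec=spec,
        block_names=tuple(block_order) if block_order is not None else tuple(names),
        sample_ids=tuple(sample_ids),
        variable_ids={n: tuple(frames[n].columns) for n in names},
        components=components,
        residuals=R,
        input_sq_norms=sq0,
        r2=R2Table(table=table),
        convergence_log=convergence_log,
    )


def fit_o2pls(dataset: MultiBlockDataset, spec: ModelSpec | None = None) -> OnPLSModel:
    """Two-block special case; delegates to :func:`fit_onpls`.

    After orthogonal filtering the global components coincide with the
    leading singular pairs of ``X_1^T X_2``.
    """
    if len(dataset.blocks) != 2:
        raise ValueError(f"O2PLS needs exactly 2 blocks, got {len(dataset.blocks)}")
    return fit_onpls(dataset, spec)


# ---------------------------------------------------------------------------
# Model summaries
# ---------------------------------------------------------------------------


def variance_decomposition(model: OnPLSModel) -> R2Table:
    """Recompute the R2 ledger from the stored components and residuals."""
    table = {}
    for n in sorted(model.block_names):
        sq = model.input_sq_norms[n]
        row = {"global": 0.0, "local": {}, "unique": 0.0}
        for c in model.components[n]:
            frac = c.variance / sq
            if c.kind == "global":
                row["global"] += frac
            elif c.kind == "local":
                row["local"][c.subset] = row["local"].get(c.subset, 0.0) + frac
            else:
                row["unique"] += frac
        row["residual"] = float(np.sum(model.residuals[n] ** 2)) / sq
        table[n] = row
    return R2Table(table=table)


def project_block(model: OnPLSModel, block_name: str, new_rows) -> np.ndarray:
    """Project new samples of one block onto its fitted components.

    ``new_rows`` must be preprocessed with the training statistics and have
    columns matching the block's variables.  Components are applied in
    extraction order with sequential deflation; the returned matrix holds
    the global-component scores (consensus order).
    """
    if isinstance(new_rows, pd.DataFrame):
        if tuple(new_rows.columns) != model.variable_ids[block_name]:
            raise ValueError(f"column ids do not match block {block_name!r} variables")
        x = new_rows.to_numpy(dtype=float)
    else:
        x = np.asarray(new_rows, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != len(model.variable_ids[block_name]):
            raise ValueError(
                f"expected {len(model.variable_ids[block_name])} variables for "
                f"block {block_name!r}, got {x.shape[1]}"
            )
    x = x.copy()
    scores: dict[int, np.ndarray] = {}
    for comp in model.components[block_name]:
        t = x @ comp.w
        x -= np.outer(t, comp.p)
        if comp.kind == "global":
            scores[comp.index] = t
    return np.column_stack([scores[i] for i in sorted(scores)])


def genotype_cv(model: OnPLSModel, design: SampleDesign) -> dict[str, float]:
    """Within-genotype spread of the first global consensus score, in percent.

    ``CV_g = 100 * sd(score | genotype g) / (max - min of the score over all
    samples)``, with the consensus score the unweighted mean of the blocks'
    first global scores.  Returns NaN per genotype when the score range is
    zero.
    """
    score = model.consensus_global_scores()[:, 0]
    rng = float(score.max() - score.min())
    out: dict[str, float] = {}
    idx = {s: i for i, s in enumerate(model.sample_ids)}
    for g in design.genotypes:
        vals = np.array([score[idx[s]] for s in design.samples_of(g)])
        if rng == 0:
            logger.warning("first global score has zero range; genotype CVs undefined")
            out[g] = float("nan")
        else:
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            out[g] = 100.0 * sd / rng
    return out
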