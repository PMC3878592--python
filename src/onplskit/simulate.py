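"""Synthetic multi-omics generator with known latent structure.

The generator emulates a small factorial field study: nine plants (three
genotypes -- a wild-type reference and two transgenic lines -- with three
biological replicates each) profiled on three platforms, giving blocks of
243 transcripts, 243 proteins and 61 metabolites by default.  Data are
built from known score and loading vectors:

* *globally joint* scores carry the genotype effect (per-component genotype
  means plus within-genotype noise), shared by all blocks;
* *locally joint* scores are shared by a proper subset of blocks
  (transcripts + proteins by default);
* *unique* scores are block-specific;
* Gaussian measurement noise is added on top.

Identifiability choices (what makes recovery exactly assertable):

* every score is orthogonalized against all previously generated scores and
  against the reference-genotype indicator, so the parts are mutually
  orthogonal in sample space and WT-reference scaling (which standardizes
  by reference statistics) preserves the part structure;
* joint signal supports are sparse (a fraction ``signal_fraction`` of the
  variables per component) and *disjoint across the joint components of a
  block*, and unique loadings live on the remaining variables, so part
  loadings stay mutually orthogonal under any per-variable rescaling.

The ground truth records the true scores, loadings, signal masks and exact
per-part variance fractions so a fitted model can be scored against it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .datamodel import MultiBlockDataset, OmicsBlock, SampleDesign
from .onpls import OnPLSModel
from .preprocessing import PreprocessParams, wt_reference_scale
from .selection import SignificanceTable

_DEFAULT_MEANS = (
    {"WT": 0.0, "LINE1": 3.0, "LINE2": 3.0},
    {"WT": 0.0, "LINE1": -2.0, "LINE2": 2.0},
)

#: all-variable-scale dimensions for performance exercises
LARGE_BLOCK_DIMS = (14619, 271, 386)


@dataclass
class SimSpec:
    """Study-design parameters of the synthetic benchmark.

    Defaults mirror the targeted three-block design: 3 genotypes x 3
    replicates, blocks of 243/243/61 variables, two genotype-structured
    global components (both lines split from the reference on component 1,
    from each other on component 2), one transcript+protein local
    component, one unique component per block, 10% sparse signal variables
    with effect loadings of magnitude at least ``min_signal_loading``,
    within-genotype score sd 0.1 and measurement noise sd 0.2.
    """

    genotypes: Mapping[str, int] = field(
        default_factory=lambda: {"WT": 3, "LINE1": 3, "LINE2": 3}
    )
    reference_genotype: str = "WT"
    block_names: tuple[str, ...] = ("transcripts", "proteins", "metabolites")
    block_dims: tuple[int, ...] = (243, 243, 61)
    n_global: int = 2
    global_genotype_means: tuple[Mapping[str, float], ...] = _DEFAULT_MEANS
    within_genotype_sd: float = 0.1
    local_parts: tuple = (((1, 2), 1),)  # (1-based block indices, count)
    n_unique: tuple[int, ...] | int = 1
    signal_fraction: float = 0.1
    loading_scale: float = 1.0
    min_signal_loading: float = 0.15
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.block_names) != len(self.block_dims):
            raise ValueError("block_names and block_dims lengths differ")
        if any(d < 1 for d in self.block_dims):
            raise ValueError("block dimensions must be positive")
        if not (0 < self.signal_fraction <= 1):
            raise ValueError("signal_fraction must be in (0, 1]")
        if self.within_genotype_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if len(self.global_genotype_means) != self.n_global:
            raise ValueError("need one genotype-mean map per global component")
        if self.reference_genotype not in self.genotypes:
            raise ValueError("reference genotype missing from genotype map")
        M = self.n_samples
        if self.total_components_max() > M - 1:
            raise ValueError(
                f"total component count {self.total_components_max()} exceeds "
                f"rank bound M-1 = {M - 1}"
            )

    @property
    def n_samples(self) -> int:
        return sum(self.genotypes.values())

    def unique_count(self, block_index: int) -> int:
        if isinstance(self.n_unique, int):
            return self.n_unique
        return self.n_unique[block_index]

    def total_components_max(self) -> int:
        per_block = []
        for i in range(len(self.block_names)):
            n_loc = sum(c for subset, c in self.local_parts if (i + 1) in subset)
            per_block.append(self.n_global + n_loc + self.unique_count(i))
        return max(per_block)


@dataclass
class GroundTruth:
    """True latent structure behind one simulated dataset."""

    design: SampleDesign
    global_scores: np.ndarray  # M x n_global
    part_scores: dict  # part key -> M-vector (includes global components)
    loadings: dict  # block -> {part key -> loading vector}
    signal_mask: dict  # block -> boolean array (global-component supports)
    part_supports: dict  # block -> {part key -> index array}
    noise_norms: dict  # block -> ||E||_F of the raw noise
    variance_fractions: dict  # block -> {"global", ("local", subset), "unique", "noise"}

    def mask_series(self, block: str, variable_ids: Sequence[str]) -> pd.Series:
        return pd.Series(self.signal_mask[block], index=list(variable_ids))


def _part_keys(spec: SimSpec) -> list[tuple]:
    """Ordered part keys: global components, local parts, unique parts."""
    keys: list[tuple] = [("global", a) for a in range(spec.n_global)]
    for subset, count in spec.local_parts:
        names = tuple(sorted(spec.block_names[i - 1] for i in subset))
        for r in range(count):
            keys.append(("local", names, r))
    for i, name in enumerate(spec.block_names):
        for r in range(spec.unique_count(i)):
            keys.append(("unique", name, r))
    return keys


def _blocks_of(spec: SimSpec, key: tuple) -> tuple[str, ...]:
    if key[0] == "global":
        return tuple(spec.block_names)
    if key[0] == "local":
        return key[1]
    return (key[1],)


def simulate_multiomics(spec: SimSpec | None = None):
    """Generate one multiblock dataset plus its ground truth.

    Returns ``(raw, scaled, truth)``: the raw signal+noise dataset, its
    WT-reference-scaled variant (the form the model normally fits), and the
    :class:`GroundTruth`.  Fully reproducible from ``spec.seed``.
    """
    spec = spec or SimSpec()
    rng = np.random.default_rng(spec.seed)
    M = spec.n_samples

    sample_ids = []
    genotype_of = {}
    replicate_index = {}
    for g, n in spec.genotypes.items():
        for r in range(1, n + 1):
            sid = f"{g}-{r}"
            sample_ids.append(sid)
            genotype_of[sid] = g
            replicate_index[sid] = r
    design = SampleDesign(
        sample_ids=tuple(sample_ids),
        genotype_of=genotype_of,
        reference_genotype=spec.reference_genotype,
        replicate_index=replicate_index,
    )
    ref_idx = np.array([genotype_of[s] == spec.reference_genotype for s in sample_ids])

    # --- scores -----------------------------------------------------------
    keys = _part_keys(spec)
    scores: dict[tuple, np.ndarray] = {}
    basis: list[np.ndarray] = []  # previously generated scores, for projection

    def _orthogonalize(t: np.ndarray, against: list[np.ndarray]) -> np.ndarray:
        """Exact projection of t onto the orthogonal complement of span(against)."""
        B = np.column_stack(against)
        coef, *_ = np.linalg.lstsq(B, t, rcond=None)
        return t - B @ coef

    for key in keys:
        if key[0] == "global":
            means = spec.global_genotype_means[key[1]]
            t = np.array([means[genotype_of[s]] for s in sample_ids], dtype=float)
            t = t + rng.normal(0.0, spec.within_genotype_sd, M)
            t = t - t[ref_idx].mean()  # reference genotype sits at the origin
        else:
            t = rng.normal(0.0, 1.0, M)
            t = _orthogonalize(t, [ref_idx.astype(float)] + basis)
            sd = t.std(ddof=0)
            if sd < 1e-10:
                raise ValueError(
                    f"orthogonalization left a zero score for part {key}; "
                    "too few samples for the requested components"
                )
            t = t / sd
        scores[key] = t
        basis.append(t)

    # --- loadings ---------------------------------------------------------
    loadings: dict[str, dict[tuple, np.ndarray]] = {n: {} for n in spec.block_names}
    supports: dict[str, dict[tuple, np.ndarray]] = {n: {} for n in spec.block_names}
    signal_mask: dict[str, np.ndarray] = {}
    for i, name in enumerate(spec.block_names):
        N = spec.block_dims[i]
        global_keys = [k for k in keys if k[0] == "global"]
        local_keys = [k for k in keys if k[0] == "local" and name in _blocks_of(spec, k)]
        unique_keys = [k for k in keys if k[0] == "unique" and k[1] == name]
        n_signal = math.ceil(spec.signal_fraction * N)
        # one shared support for the global components, one disjoint support
        # per local part, unique loadings on the remaining variables: parts
        # stay loading-orthogonal under any per-variable rescaling
        n_supports = 1 + len(local_keys)
        if n_signal * n_supports > N:
            raise ValueError(
                f"block {name!r}: {n_supports} signal supports x "
                f"{n_signal} variables exceed N={N}"
            )
        perm = rng.permutation(N)
        global_idx = np.sort(perm[:n_signal])
        pos = n_signal
        for k in global_keys:
            v = rng.normal(0.0, spec.loading_scale, n_signal)
            v = np.sign(v) * np.maximum(np.abs(v), spec.min_signal_loading)
            p = np.zeros(N)
            p[global_idx] = v
            loadings[name][k] = p
            supports[name][k] = global_idx
        for k in local_keys:
            idx = np.sort(perm[pos: pos + n_signal])
            pos += n_signal
            v = rng.normal(0.0, spec.loading_scale, n_signal)
            v = np.sign(v) * np.maximum(np.abs(v), spec.min_signal_loading)
            p = np.zeros(N)
            p[idx] = v
            loadings[name][k] = p
            supports[name][k] = idx
        rest = np.sort(perm[pos:])
        for k in unique_keys:
            p = np.zeros(N)
            if len(rest):
                p[rest] = rng.normal(0.0, spec.loading_scale, len(rest))
            loadings[name][k] = p
            supports[name][k] = rest
        mask = np.zeros(N, dtype=bool)
        mask[global_idx] = True
        signal_mask[name] = mask

    # --- assemble blocks --------------------------------------------------
    raw_blocks: list[OmicsBlock] = []
    scaled_blocks: list[OmicsBlock] = []
    noise_norms: dict[str, float] = {}
    variance_fractions: dict[str, dict] = {}
    params = PreprocessParams()
    for i, name in enumerate(spec.block_names):
        N = spec.block_dims[i]
        X = np.zeros((M, N))
        for k, p in loadings[name].items():
            X += np.outer(scores[k], p)
        E = rng.normal(0.0, spec.noise_sd, (M, N)) if spec.noise_sd > 0 else np.zeros((M, N))
        X = X + E
        noise_norms[name] = float(np.linalg.norm(E))
        var_ids = [f"{name[0].upper()}{j + 1:05d}" for j in range(N)]
        df = pd.DataFrame(X, index=sample_ids, columns=var_ids)
        raw = OmicsBlock(name=name, data=df, platform="synthetic", state="raw")
        raw_blocks.append(raw)
        scaled_blocks.append(wt_reference_scale(raw, design, params))

        # exact part-wise energies of the raw matrix (scores are orthogonal
        # across parts, so cross terms vanish and the fractions are exact)
        energies = {}
        for k, p in loadings[name].items():
            energies[k] = float(scores[k] @ scores[k]) * float(p @ p)
        noise_energy = float(np.sum(E * E))
        total = sum(energies.values()) + noise_energy
        fr = {"global": 0.0, "unique": 0.0, "noise": noise_energy / total}
        for k, e in energies.items():
            if k[0] == "global":
                fr["global"] += e / total
            elif k[0] == "local":
                fr[("local", k[1])] = fr.get(("local", k[1]), 0.0) + e / total
            else:
                fr["unique"] += e / total
        variance_fractions[name] = fr

    raw_ds = MultiBlockDataset(design=design, blocks=raw_blocks)
    scaled_ds = MultiBlockDataset(design=design, blocks=scaled_blocks)
    truth = GroundTruth(
        design=design,
        global_scores=np.column_stack([scores[("global", a)] for a in range(spec.n_global)]),
        part_scores=scores,
        loadings=loadings,
        signal_mask=signal_mask,
        part_supports=supports,
        noise_norms=noise_norms,
        variance_fractions=variance_fractions,
    )
    return raw_ds, scaled_ds, truth


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------


def evaluate_recovery(
    model: OnPLSModel,
    truth: GroundTruth,
    significance: Mapping[str, SignificanceTable] | None = None,
) -> dict:
    """Score a fitted model against the generator's ground truth.

    Reports the principal angles (radians) between the true and estimated
    global score subspaces, the absolute error of each R2 part against the
    true variance fractions, and -- when significance tables are supplied --
    the confusion matrix of the selection against the signal mask.
    """
    if len(model.sample_ids) != truth.global_scores.shape[0]:
        raise ValueError(
            f"model has {len(model.sample_ids)} samples but truth has "
            f"{truth.global_scores.shape[0]}"
        )
    est = model.consensus_global_scores()
    angles = scipy.linalg.subspace_angles(truth.global_scores, est)
    report: dict = {
        "principal_angles": np.sort(angles)[::-1],
        "max_principal_angle": float(np.max(angles)),
    }

    r2_errors: dict[str, dict] = {}
    for name in sorted(model.block_names):
        row = model.r2.row(name)
        fr = truth.variance_fractions[name]
        err = {
            "global": abs(row["global"] - fr.get("global", 0.0)),
            "unique": abs(row["unique"] - fr.get("unique", 0.0)),
            "residual_vs_noise": abs(row["residual"] - fr.get("noise", 0.0)),
        }
        locals_true = {k[1]: v for k, v in fr.items() if isinstance(k, tuple) and k[0] == "local"}
        for subset in set(row["local"]) | set(locals_true):
            err[("local", subset)] = abs(
                row["local"].get(subset, 0.0) - locals_true.get(subset, 0.0)
            )
        r2_errors[name] = err
    report["r2_abs_errors"] = r2_errors
    report["max_r2_error"] = max(
        v for err in r2_errors.values() for v in err.values()
    )

    if significance is not None:
        tp = fp = fn = tn = 0
        for name, table in significance.items():
            mask = truth.mask_series(name, table.table.index)
            called = table.table["significant"].astype(bool)
            tp += int((called & mask).sum())
            fp += int((called & ~mask).sum())
            fn += int((~called & mask).sum())
            tn += int((~called & ~mask).sum())
        report["confusion"] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
        report["sensitivity"] = tp / (tp + fn) if tp + fn else float("nan")
        report["specificity"] = tn / (tn + fp) if tn + fp else float("nan")
    return report


def write_truth_json(truth: GroundTruth, path: str | Path) -> None:
    """Serialize the ground truth (scores, masks, fractions) as JSON."""
    def _key(k) -> str:
        if isinstance(k, tuple):
            return ":".join(_key(x) for x in k)
        return str(k)

    payload = {
        "sample_ids": list(truth.design.sample_ids),
        "global_scores": truth.global_scores.tolist(),
        "part_scores": {_key(k): v.tolist() for k, v in truth.part_scores.items()},
        "signal_mask": {b: m.astype(int).tolist() for b, m in truth.signal_mask.items()},
        "noise_norms": truth.noise_norms,
        "variance_fractions": {
            b: {_key(k): v for k, v in fr.items()}
            for b, fr in truth.variance_fractions.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
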