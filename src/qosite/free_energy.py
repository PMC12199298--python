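"""Free-energy profiles over torsions and distance pairs.

Samples (optionally carrying importance weights that remove a metadynamics
bias) are binned into 1D or 2D histograms; bin probabilities map to
DeltaG = -kT ln p shifted so the global minimum is zero.  Empty bins are
masked, never extrapolated.  Replicas on identical binning combine into a
mean profile with a per-bin standard error.

kT defaults to 2.5775 kJ/mol (R*T at 310 K).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import ValidationError
from .synthetic import KT_310

__all__ = [
    "FreeEnergyProfile",
    "SampleSet",
    "combine_replicas",
    "concat_sample_sets",
    "marginalize",
    "profile_from_samples",
    "reweight_metadynamics",
    "weighted_histogram",
]


@dataclass
class SampleSet:
    """Collective-variable samples with per-frame positive weights.

    ``values`` is (n,) for one CV or (n, 2) for two; unbiased frames carry
    weight 1.
    """

    values: np.ndarray
    weights: np.ndarray | None = None
    kT: float = KT_310

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (1, 2) or (self.values.ndim == 2 and self.values.shape[1] != 2):
            raise ValidationError("values must be (n,) or (n, 2)")
        n = len(self.values)
        if self.weights is None:
            self.weights = np.ones(n)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != n:
            raise ValidationError("values and weights must have equal length")
        if not np.all(self.weights > 0):
            raise ValidationError("weights must be positive")
        if self.kT <= 0:
            raise ValidationError("kT must be positive")

    @property
    def ndim(self) -> int:
        return 1 if self.values.ndim == 1 else 2


def weighted_histogram(samples: SampleSet, edges) -> np.ndarray:
    """Weighted bin probabilities normalised over in-range samples.

    ``edges`` is a 1D edge array, or a pair of edge arrays for 2D samples.
    """
    if samples.ndim == 1:
        h, _ = np.histogram(samples.values, bins=np.asarray(edges, dtype=float), weights=samples.weights)
    else:
        ex, ey = (np.asarray(e, dtype=float) for e in edges)
        h, _, _ = np.histogram2d(samples.values[:, 0], samples.values[:, 1], bins=(ex, ey), weights=samples.weights)
    total = h.sum()
    if total <= 0:
        raise ValidationError("no samples fall inside the histogram range")
    return h / total


@dataclass
class FreeEnergyProfile:
    """Binned DeltaG (kJ/mol) with per-bin SE and an empty-bin mask.

    ``mask`` is True where a bin is empty (no DeltaG value; stored as NaN).
    ``prob`` retains the bin probabilities so profiles can be marginalised.
    """

    edges: np.ndarray | tuple[np.ndarray, np.ndarray]
    dG: np.ndarray
    mask: np.ndarray
    se: np.ndarray | None = None
    prob: np.ndarray | None = None
    kT: float = KT_310

    def __post_init__(self) -> None:
        self.dG = np.asarray(self.dG, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.dG.shape != self.mask.shape:
            raise ValidationError("dG and mask shapes differ")
        if self.se is not None and np.asarray(self.se).shape != self.dG.shape:
            raise ValidationError("se shape differs from dG")

    @property
    def ndim(self) -> int:
        return self.dG.ndim

    def centers(self, axis: int = 0) -> np.ndarray:
        e = self.edges[axis] if isinstance(self.edges, tuple) else np.asarray(self.edges)
        e = np.asarray(e, dtype=float)
        return 0.5 * (e[:-1] + e[1:])


def profile_from_samples(samples: SampleSet, edges) -> FreeEnergyProfile:
    """DeltaG = -kT ln p per bin, min-shifted to zero; empty bins masked."""
    p = weighted_histogram(samples, edges)
    mask = p <= 0
    dG = np.full(p.shape, np.nan)
    with np.errstate(divide="ignore"):
        dG[~mask] = -samples.kT * np.log(p[~mask])
    dG[~mask] -= np.nanmin(dG[~mask])
    stored = (np.asarray(edges[0], float), np.asarray(edges[1], float)) if samples.ndim == 2 else np.asarray(edges, float)
    return FreeEnergyProfile(edges=stored, dG=dG, mask=mask, prob=p, kT=samples.kT)


def reweight_metadynamics(values, bias_at_samples, kT: float = KT_310) -> SampleSet:
    """Remove a metadynamics bias by importance weights w_i ∝ exp(+V(s_i)/kT).

    ``bias_at_samples`` is the final accumulated bias (kJ/mol) evaluated at
    each sample's CV value.  A constant bias yields uniform weights.
    """
    values = np.asarray(values, dtype=float)
    bias = np.asarray(bias_at_samples, dtype=float)
    if len(bias) != len(values):
        raise ValidationError("bias array length must match values")
    if not np.all(np.isfinite(bias)):
        raise ValidationError("bias values must be finite")
    # subtracting the max keeps exp() in range; weights are defined up to scale
    w = np.exp((bias - bias.max()) / kT)
    w /= w.mean()
    return SampleSet(values=values, weights=w, kT=kT)


def concat_sample_sets(sets: Sequence[SampleSet]) -> SampleSet:
    """Concatenate trajectories with equal-time weighting.

    Each input's weights are rescaled to sum to its own frame count before
    concatenation, so a biased replica and an unbiased replica of equal
    length contribute equally to the combined surface.
    """
    if not sets:
        raise ValidationError("nothing to concatenate")
    kT = sets[0].kT
    vals, wts = [], []
    for s in sets:
        if abs(s.kT - kT) > 1e-9:
            raise ValidationError("all sample sets must share kT")
        vals.append(s.values)
        wts.append(s.weights * (len(s.values) / s.weights.sum()))
    return SampleSet(values=np.concatenate(vals), weights=np.concatenate(wts), kT=kT)


def combine_replicas(profiles: Sequence[FreeEnergyProfile]) -> FreeEnergyProfile:
    """Mean profile over replicas with SE = sd/sqrt(n) per bin.

    Requires identical bin edges; a bin masked in any replica is masked in
    the result.  With n = 2 replicas (the usual pair of independent
    metadynamics runs) the SE is reported as-is, but is itself a noisy
    estimate.
    """
    if len(profiles) < 2:
        raise ValidationError("need at least two replicas")
    ref = profiles[0]

    def _edges_list(p):
        return list(p.edges) if isinstance(p.edges, tuple) else [p.edges]

    for p in profiles[1:]:
        ea, eb = _edges_list(ref), _edges_list(p)
        if len(ea) != len(eb) or any(not np.array_equal(x, y) for x, y in zip(ea, eb)):
            raise ValidationError("replicas must share identical bin edges")
    stack = np.stack([p.dG for p in profiles])
    mask = np.any(np.stack([p.mask for p in profiles]), axis=0)
    n = len(profiles)
    mean = np.full(ref.dG.shape, np.nan)
    se = np.full(ref.dG.shape, np.nan)
    mean[~mask] = stack.mean(axis=0)[~mask]
    se[~mask] = stack.std(axis=0, ddof=1)[~mask] / np.sqrt(n)
    if np.any(~mask):
        mean[~mask] -= np.nanmin(mean[~mask])
    prob = None
    if all(p.prob is not None for p in profiles):
        prob = np.stack([p.prob for p in profiles]).mean(axis=0)
    return FreeEnergyProfile(edges=ref.edges, dG=mean, mask=mask, se=se, prob=prob, kT=ref.kT)


def marginalize(profile: FreeEnergyProfile, axis: int) -> FreeEnergyProfile:
    """Marginalise a 2D profile over one axis by summing bin probabilities."""
    if profile.ndim != 2 or profile.prob is None:
        raise ValidationError("marginalize needs a 2D profile with stored probabilities")
    p = profile.prob.sum(axis=axis)
    mask = p <= 0
    dG = np.full(p.shape, np.nan)
    dG[~mask] = -profile.kT * np.log(p[~mask])
    dG[~mask] -= np.nanmin(dG[~mask])
    kept = profile.edges[1 - axis]
    return FreeEnergyProfile(edges=np.asarray(kept), dG=dG, mask=mask, prob=p, kT=profile.kT)
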