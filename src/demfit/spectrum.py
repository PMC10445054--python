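"""Allele-frequency spectra and the Poisson composite likelihood.

An :class:`AFS` holds a 1- or 2-dimensional array indexed by derived (or
minor, when folded) allele counts, together with the per-population haploid
sample sizes, a boolean exclusion mask and the folded flag.  The monomorphic
corner bins are always masked: the composite likelihood is defined over
segregating variants only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "AFS", "InbreedingParams", "project", "fold", "marginalize",
    "apply_inbreeding", "poisson_loglik", "optimal_theta",
]


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


class AFS:
    """A k-dimensional allele-frequency spectrum (k in {1, 2})."""

    def __init__(self, data, folded=False, mask=None, pop_labels=None):
        data = np.asarray(data, dtype=float)
        if data.ndim not in (1, 2):
            raise ValueError("only 1- and 2-dimensional spectra are supported")
        self.data = data
        self.folded = bool(folded)
        self.sample_sizes = tuple(s - 1 for s in data.shape)
        if any(n < 1 for n in self.sample_sizes):
            raise ValueError("each axis needs at least 2 entries")
        if mask is None:
            mask = np.zeros(data.shape, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool).copy()
            if mask.shape != data.shape:
                raise ValueError("mask shape mismatch")
        mask |= self.default_mask(data.shape, self.folded)
        self.mask = mask
        if pop_labels is not None:
            pop_labels = tuple(pop_labels)
            if len(pop_labels) != data.ndim:
                raise ValueError("one population label per axis required")
        self.pop_labels = pop_labels
        unmasked = self.data[~self.mask]
        if unmasked.size and not np.all(np.isfinite(unmasked)):
            raise ValueError("unmasked entries must be finite")

    @staticmethod
    def default_mask(shape, folded):
        """Corner bins, plus the majority bins of a folded spectrum."""
        mask = np.zeros(shape, dtype=bool)
        mask[(0,) * len(shape)] = True
        mask[tuple(s - 1 for s in shape)] = True
        if folded:
            n_total = sum(s - 1 for s in shape)
            totals = np.zeros(shape)
            for axis, s in enumerate(shape):
                idx = [None] * len(shape)
                idx[axis] = slice(None)
                totals = totals + np.arange(s)[tuple(idx)]
            mask |= totals > n_total / 2.0
        return mask

    @property
    def ndim(self):
        return self.data.ndim

    def copy(self):
        return AFS(self.data.copy(), folded=self.folded, mask=self.mask.copy(),
                   pop_labels=self.pop_labels)

    def S(self):
        """Total unmasked (segregating) mass."""
        return float(self.data[~self.mask].sum())

    def __mul__(self, c):
        return AFS(self.data * float(c), folded=self.folded,
                   mask=self.mask.copy(), pop_labels=self.pop_labels)

    __rmul__ = __mul__

    def __repr__(self):
        kind = "folded" if self.folded else "unfolded"
        return (f"AFS(sample_sizes={self.sample_sizes}, {kind}, "
                f"S={self.S():.6g})")


# ---------------------------------------------------------------------------
# transforms


def projection_matrix(n_from: int, n_to: int) -> np.ndarray:
    """Hypergeometric downsampling matrix, entry [i, j] = P(j of n_to | i of n_from)."""
    if n_to > n_from:
        raise ValueError("cannot project to a larger sample size")
    i = np.arange(n_from + 1)[:, None]
    j = np.arange(n_to + 1)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = (_log_comb(i, j) + _log_comb(n_from - i, n_to - j)
                - _log_comb(n_from, n_to))
    p = np.where((j <= i) & (n_to - j <= n_from - i), np.exp(logp), 0.0)
    return p


def project(afs: AFS, new_sizes) -> AFS:
    """Hypergeometric expectation of subsampling without replacement.

    Projecting an axis to size 0 marginalizes that population out.
    """
    if afs.folded:
        raise ValueError("projection requires an unfolded spectrum")
    new_sizes = tuple(int(n) for n in np.atleast_1d(new_sizes))
    if len(new_sizes) != afs.ndim:
        raise ValueError("one target size per population required")
    data = afs.data
    keep = []
    labels = afs.pop_labels
    for axis, (n_from, n_to) in enumerate(zip(afs.sample_sizes, new_sizes)):
        if n_to > n_from:
            raise ValueError(
                f"cannot project axis {axis} from {n_from} up to {n_to}")
        if n_to > 0:
            keep.append(axis)
        data = np.moveaxis(
            np.tensordot(np.moveaxis(data, axis, 0), projection_matrix(n_from, n_to),
                         axes=([0], [0])), -1, axis)
    removed = [a for a in range(afs.ndim) if a not in keep]
    for axis in sorted(removed, reverse=True):
        data = np.squeeze(data, axis=axis)
        if labels is not None:
            labels = tuple(l for k, l in enumerate(labels) if k != axis)
    if data.ndim == 0:
        raise ValueError("cannot marginalize every population out")
    return AFS(data, folded=False, pop_labels=labels)


def marginalize(afs: AFS, axis: int) -> AFS:
    """Remove one population by projecting it to size 0."""
    sizes = list(afs.sample_sizes)
    sizes[axis] = 0
    return project(afs, sizes)


def fold(afs: AFS) -> AFS:
    """Collapse a spectrum over unknown ancestral state.

    The bin at minor count ``i`` receives the derived-count masses ``i`` and
    ``n - i``; self-complementary bins are unchanged; majority bins are
    masked.  Folding a folded spectrum returns it unchanged with a warning.
    """
    if afs.folded:
        warnings.warn("spectrum is already folded", stacklevel=2)
        return afs.copy()
    rev = tuple(slice(None, None, -1) for _ in range(afs.ndim))
    data = afs.data + afs.data[rev]
    n_total = sum(afs.sample_sizes)
    totals = np.zeros(afs.data.shape)
    for axis, s in enumerate(afs.data.shape):
        idx = [None] * afs.ndim
        idx[axis] = slice(None)
        totals = totals + np.arange(s)[tuple(idx)]
    data = np.where(totals == n_total / 2.0, 0.5 * data, data)
    mask = afs.mask | afs.mask[rev]
    return AFS(data, folded=True, mask=mask, pop_labels=afs.pop_labels)


@dataclass(frozen=True)
class InbreedingParams:
    """Per-population inbreeding coefficients and diploid sample counts."""

    F: tuple
    n_diploid: tuple

    def __post_init__(self):
        object.__setattr__(self, "F", tuple(float(f) for f in np.atleast_1d(self.F)))
        object.__setattr__(self, "n_diploid",
                           tuple(int(n) for n in np.atleast_1d(self.n_diploid)))
        if len(self.F) != len(self.n_diploid):
            raise ValueError("F and n_diploid must have equal lengths")
        for f in self.F:
            if not 0.0 <= f <= 1.0:
                raise ValueError("inbreeding coefficients must lie in [0, 1]")


def _inbreeding_matrix(n: int, F: float) -> np.ndarray:
    """Linear map from the 2n-haploid spectrum to diploid derived counts 0..2n.

    Mixture over ``j ~ Binomial(n, F)`` inbred individuals: each inbred
    individual contributes a single sampled allele counted twice, outbred
    individuals contribute two independent alleles.  With ``j`` inbred the
    effective haploid draw is ``m = 2n - j``; which of the ``m`` draws are
    doubled is exchangeable, giving a hypergeometric redistribution.
    """
    two_n = 2 * n
    log_bin = (_log_comb(n, np.arange(n + 1)) +
               np.arange(n + 1) * (np.log(F) if F > 0 else 0.0) +
               (n - np.arange(n + 1)) * (np.log1p(-F) if F < 1 else 0.0))
    W = np.zeros((two_n + 1, two_n + 1))
    for j in range(n + 1):
        if F == 0.0 and j > 0:
            continue
        if F == 1.0 and j < n:
            continue
        w = 1.0 if F in (0.0, 1.0) else float(np.exp(log_bin[j]))
        m = two_n - j
        P = projection_matrix(two_n, m)
        k = np.arange(m + 1)[:, None]
        a = np.arange(j + 1)[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            loghg = (_log_comb(k, a) + _log_comb(m - k, j - a) - _log_comb(m, j))
        hg = np.where((a <= k) & (j - a <= m - k), np.exp(loghg), 0.0)
        R = np.zeros((m + 1, two_n + 1))
        for kk in range(m + 1):
            for aa in range(min(j, kk) + 1):
                R[kk, kk + aa] += hg[kk, aa]
        W += w * (P @ R)
    return W


def apply_inbreeding(afs: AFS, params: InbreedingParams) -> AFS:
    """Transform a haploid expected spectrum to diploid-derived counts.

    Input axes must have haploid size ``2 n_diploid`` per population; the
    output has the same shape, indexed by diploid derived-allele counts
    ``0..2n``.  ``F = 0`` reduces exactly to the haploid spectrum.
    """
    if afs.folded:
        raise ValueError("apply inbreeding before folding")
    if len(params.F) != afs.ndim:
        raise ValueError("one inbreeding coefficient per population required")
    data = afs.data
    for axis, (F, n) in enumerate(zip(params.F, params.n_diploid)):
        if afs.sample_sizes[axis] != 2 * n:
            raise ValueError(
                f"axis {axis}: expected haploid size {2 * n}, "
                f"got {afs.sample_sizes[axis]}")
        if F == 0.0:
            continue
        W = _inbreeding_matrix(n, F)
        data = np.moveaxis(
            np.tensordot(np.moveaxis(data, axis, 0), W, axes=([0], [0])),
            -1, axis)
    return AFS(data, folded=False, pop_labels=afs.pop_labels)


# ---------------------------------------------------------------------------
# likelihood


def _check_compatible(model: AFS, data: AFS):
    if model.data.shape != data.data.shape:
        raise ValueError(
            f"shape mismatch: model {model.data.shape} vs data {data.data.shape}")
    if model.folded != data.folded:
        raise ValueError("model and data disagree on folding")


def poisson_loglik(model: AFS, data: AFS) -> float:
    """Poisson random-field composite log-likelihood.

    Sum over unmasked bins of ``d ln m - m - ln Gamma(d + 1)``; data bins may
    be non-integer (projected spectra).  Returns ``-inf`` when the model
    assigns zero mass to an observed bin.
    """
    _check_compatible(model, data)
    keep = ~(model.mask | data.mask)
    m = model.data[keep]
    d = data.data[keep]
    if np.any(m < 0):
        raise ValueError("model entries must be non-negative")
    if np.any((m == 0) & (d > 0)):
        return float("-inf")
    pos = m > 0
    return float(np.sum(d[pos] * np.log(m[pos]) - m[pos] - gammaln(d[pos] + 1))
                 - np.sum(gammaln(d[~pos] + 1)))


def optimal_theta(model: AFS, data: AFS) -> float:
    """Poisson-MLE multiplicative scale for a per-unit-theta model spectrum."""
    _check_compatible(model, data)
    keep = ~(model.mask | data.mask)
    denom = float(model.data[keep].sum())
    if denom <= 0:
        raise ValueError("model spectrum has zero unmasked mass")
    return float(data.data[keep].sum()) / denom
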