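"""Coordinative structure by per-strike PCA of joint-angle covariation.

Each striking movement is decomposed as

    phi_i(t) - phi_Mi = sum_k w_ki xi_k(t)

an eigendecomposition of the 9 x 9 covariance matrix of the joint-angle
channels across the frames of that strike (covariance, not correlation: all
channels share degree units, so their scales are commensurate and the
decomposition reflects the actual covariation synergy). PC1 is the joint-
space direction along which the movement covaries most; its loadings
``w_1i`` describe the relative joint contributions. The regularity of a
subject's coordination across successful strikes is measured by the
absolute Pearson correlation of PC1 loadings between strike pairs,
significant above 0.7 — and required in *all* pairs for a "consistent
coordination" verdict.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io import RunConfig
from .reconstruction import JointAngleSeries


@dataclass
class SynergyDecomposition:
    """Per-strike PCA: orthonormal loadings (9 x k columns), component time
    series, variance fractions (descending, summing to 1) and channel means."""

    loadings: np.ndarray  # (9, 9), column k = w_k
    components: np.ndarray  # (n_frames, 9), xi_k(t)
    variance_fractions: np.ndarray  # (9,)
    channel_means: np.ndarray  # (9,) deg
    n_frames: int

    @property
    def pc1(self) -> np.ndarray:
        return self.loadings[:, 0]

    def reconstruct(self, k: Optional[int] = None) -> np.ndarray:
        """Angles rebuilt from the first ``k`` components (all 9 -> exact)."""
        k = 9 if k is None else k
        return self.components[:, :k] @ self.loadings[:, :k].T + self.channel_means


def pca_strike(
    angles: JointAngleSeries,
    segment: Optional[slice] = None,
    standardize: bool = False,
) -> SynergyDecomposition:
    """PCA of one striking movement.

    Channels are mean-centered over the segment frames; the covariance
    matrix (n-1 denominator) is eigendecomposed; eigenvalues are sorted
    descending and each loading column is sign-normalized so its largest-
    magnitude element is positive. ``standardize=True`` switches to the
    correlation matrix (off by default; the covariation matrix is the
    analysis-defining choice).
    """
    x = angles.angles_deg if segment is None else angles.angles_deg[segment]
    if x.shape[0] < 10:
        raise ValueError("per-strike PCA needs at least 10 frames")
    if x.shape[1] != 9:
        raise ValueError("expected 9 joint-angle channels")
    means = x.mean(axis=0)
    centered = x - means
    if standardize:
        sd = centered.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant channel: correlation-matrix PCA undefined")
        centered = centered / sd
    cov = centered.T @ centered / (x.shape[0] - 1)
    total = float(np.trace(cov))
    if total <= 0:
        raise ValueError("all channels constant over the segment: PCA undefined")
    evals, evecs = np.linalg.eigh(cov)
    idx = np.argsort(evals)[::-1]
    evals = np.clip(evals[idx], 0.0, None)
    evecs = evecs[:, idx]
    # fix sign: largest-|.| element of each loading vector positive
    for k in range(evecs.shape[1]):
        j = int(np.argmax(np.abs(evecs[:, k])))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    components = centered @ evecs
    return SynergyDecomposition(
        loadings=evecs,
        components=components,
        variance_fractions=evals / evals.sum(),
        channel_means=means,
        n_frames=x.shape[0],
    )


def explained_variance_summary(
    decompositions: Sequence[SynergyDecomposition],
    grouping: Optional[Sequence[str]] = None,
    adequacy_percent: float = 90.0,
) -> dict:
    """Summary of PC1/PC2 explained-variance percentages, overall and per
    group; groups whose PC1+PC2 mean falls below the adequacy line (default
    90%) are flagged as insufficiently compressed."""
    if len(decompositions) == 0:
        raise ValueError("no decompositions to summarize")
    pc1 = np.array([d.variance_fractions[0] * 100 for d in decompositions])
    pc2 = np.array([d.variance_fractions[1] * 100 for d in decompositions])

    def _summ(v: np.ndarray) -> dict:
        return {
            "mean": float(v.mean()),
            "median": float(np.median(v)),
            "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
            "min": float(v.min()),
            "max": float(v.max()),
        }

    out = {"overall": {"pc1": _summ(pc1), "pc2": _summ(pc2)}, "groups": {}, "flagged": []}
    if grouping is not None:
        grouping = np.asarray(grouping)
        for g in dict.fromkeys(grouping):  # preserve order
            mask = grouping == g
            g1, g2 = pc1[mask], pc2[mask]
            out["groups"][g] = {"pc1": _summ(g1), "pc2": _summ(g2)}
            if (g1 + g2).mean() < adequacy_percent:
                out["flagged"].append(g)
    return out


@dataclass
class LoadingComparison:
    strike_a: int
    strike_b: int
    abs_r: float
    significant: bool


def compare_pc1_loadings(
    decompositions: Sequence[SynergyDecomposition],
    config: Optional[RunConfig] = None,
) -> tuple[list[LoadingComparison], Optional[bool]]:
    """All pairwise |Pearson r| between PC1 loadings of a subject's
    successful strikes, and the subject-level verdict: consistent
    coordination only if **all** pairs exceed the cutoff (default 0.7).

    With fewer than two strikes the verdict is undefined (None).
    """
    config = config or RunConfig()
    if len(decompositions) < 2:
        return [], None
    comps: list[LoadingComparison] = []
    for i, j in combinations(range(len(decompositions)), 2):
        r = stats.pearsonr(decompositions[i].pc1, decompositions[j].pc1).statistic
        abs_r = float(abs(r))
        comps.append(
            LoadingComparison(
                strike_a=i,
                strike_b=j,
                abs_r=abs_r,
                significant=bool(abs_r > config.loading_r_cutoff),
            )
        )
    return comps, all(c.significant for c in comps)
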