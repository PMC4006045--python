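"""Task performance: flake-mass statistics, expertise allocation, and
pairwise group inference.

Flake-mass variability is the primary indicator of task performance: an
actor who understands the functional dynamics of flake removal produces
flakes of the intended size consistently. The coefficient of variation is
``CV = SD / mean * 100`` (percent); group differences are tested with
Welch t-tests over all pairs at a Bonferroni-adjusted level ``alpha / 6``
for four groups, one-sided (decreasing with expertise) for CV, two-sided
for the energy measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
from scipy import stats

from .io import RunConfig

GROUP_ORDER = ("uninitiated", "novice", "intermediate", "expert")


@dataclass
class FlakeStats:
    """Sample statistics of flake masses in grams."""

    n: int
    mean: float
    median: float
    sd: float
    min: float
    max: float

    @property
    def range(self) -> tuple[float, float]:
        return (self.min, self.max)

    @property
    def cv(self) -> float:
        """SD / mean * 100 (%); undefined (nan) for zero mean."""
        if self.mean == 0:
            return float("nan")
        return self.sd / self.mean * 100.0


def flake_statistics(masses) -> FlakeStats:
    """Standard sample statistics; SD uses the n-1 denominator (0 for n=1)."""
    masses = np.asarray(masses, dtype=float)
    masses = masses[np.isfinite(masses)]
    if masses.size == 0:
        raise ValueError("flake_statistics needs at least one mass")
    sd = float(masses.std(ddof=1)) if masses.size > 1 else 0.0
    return FlakeStats(
        n=int(masses.size),
        mean=float(masses.mean()),
        median=float(np.median(masses)),
        sd=sd,
        min=float(masses.min()),
        max=float(masses.max()),
    )


# ---------------------------------------------------------------------------
# expertise allocation
# ---------------------------------------------------------------------------

LABELS = ("uninitiated", "novice", "intermediate", "expert")


@dataclass
class ExpertiseLabel:
    """Skill allocation with the full rule trace that produced it."""

    label: str
    trace: list[str] = field(default_factory=list)


def classify_expertise(
    per_condition_stats: dict[str, FlakeStats],
    config: Optional[RunConfig] = None,
) -> ExpertiseLabel:
    """Allocate a skill level from small- and large-flake outcome statistics.

    Rules, in order (all thresholds configurable):

    * a size is "met" when the median mass lies within a multiplicative band
      (default x/÷ 2) of the model mass (default 12 g small, 50 g large);
    * neither size met -> uninitiated;
    * exactly one size met -> novice (regular production of only one size);
    * both met -> intermediate, promoted to expert when production is also
      regular: pooled CV <= the cutoff (default 65%).
    """
    config = config or RunConfig()
    for size in ("small", "large"):
        if size not in per_condition_stats:
            raise ValueError(f"missing per-condition statistics for '{size}' flakes")
    trace: list[str] = []
    met: dict[str, bool] = {}
    for size, model_mass in (
        ("small", config.small_model_mass_g),
        ("large", config.large_model_mass_g),
    ):
        st = per_condition_stats[size]
        lo, hi = model_mass / config.size_band_factor, model_mass * config.size_band_factor
        met[size] = lo <= st.median <= hi
        trace.append(
            f"{size}: median {st.median:.1f} g vs band [{lo:.1f}, {hi:.1f}] g -> "
            f"{'met' if met[size] else 'not met'}"
        )
    if not met["small"] and not met["large"]:
        trace.append("neither size met -> uninitiated")
        return ExpertiseLabel("uninitiated", trace)
    if met["small"] != met["large"]:
        trace.append("only one size achievable -> novice")
        return ExpertiseLabel("novice", trace)
    cvs = [per_condition_stats[s].cv for s in ("small", "large")]
    cv = float(np.nanmean(cvs))
    trace.append(f"both sizes met; mean CV {cv:.0f}%")
    if cv <= config.expert_cv_cutoff_percent:
        trace.append(f"CV <= {config.expert_cv_cutoff_percent:.0f}% -> expert")
        return ExpertiseLabel("expert", trace)
    trace.append(f"CV > {config.expert_cv_cutoff_percent:.0f}% -> intermediate")
    return ExpertiseLabel("intermediate", trace)


# ---------------------------------------------------------------------------
# pairwise group tests
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    one_sided: bool
    alpha_adjusted: float
    significant: bool
    n_a: int = 0
    n_b: int = 0


def pairwise_group_tests(
    values_by_group: dict[str, np.ndarray],
    one_sided: bool = False,
    config: Optional[RunConfig] = None,
    order: tuple[str, ...] = GROUP_ORDER,
) -> list[GroupComparison]:
    """Welch t-tests over all group pairs at the Bonferroni-adjusted level.

    ``one_sided=True`` tests the directional hypothesis that the value
    decreases with expertise (less-expert group greater), used for CV;
    two-sided otherwise. Groups with fewer than 2 values are excluded
    (their pairs are dropped, not failed).
    """
    config = config or RunConfig()
    rank = {g: i for i, g in enumerate(order)}
    names = sorted(values_by_group, key=lambda g: rank.get(g, len(order)))
    alpha_adj = config.alpha_adjusted
    out: list[GroupComparison] = []
    for a, b in combinations(names, 2):
        va = np.asarray(values_by_group[a], dtype=float)
        vb = np.asarray(values_by_group[b], dtype=float)
        va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
        if len(va) < 2 or len(vb) < 2:
            continue
        alternative = "greater" if one_sided else "two-sided"
        res = stats.ttest_ind(va, vb, equal_var=False, alternative=alternative)
        out.append(
            GroupComparison(
                group_a=a,
                group_b=b,
                statistic=float(res.statistic),
                p_value=float(res.pvalue),
                one_sided=one_sided,
                alpha_adjusted=alpha_adj,
                significant=bool(res.pvalue < alpha_adj),
                n_a=len(va),
                n_b=len(vb),
            )
        )
    return out
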