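"""Oxic-versus-anoxic network expansion metrics and the aerobe/anaerobe test.

The increase rate of a species is the ratio of the total number of classified
enzymes (or metabolites) in its network to the number of anoxic ones — i.e.
how much larger the oxygen-enabled network is than the metabolic space that
is available without oxygen.  Aerobes and anaerobes are compared with a
two-tailed Wilcoxon–Mann–Whitney test and an ordinary two-group linear model
(rate ~ indicator of aerobiosis); the phylogenetically controlled
counterpart lives in :mod:`oxymet.phylo_comparative`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.stats as st
import statsmodels.api as sm

from .data_model_io import OxygenClassification, SpeciesNetwork
from .errors import ValidationError

#: maximum pooled sample size for the exact WMW null distribution
EXACT_WMW_LIMIT = 20


@dataclass(frozen=True)
class ExpansionResult:
    organism_id: str
    basis: str  # enzyme | metabolite
    n_total: int
    n_anoxic: int
    increase_rate: float  # NaN when undefined
    undefined: bool = False


@dataclass(frozen=True)
class GroupComparison:
    group_a_label: str
    group_b_label: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    wmw_p: float
    lm_estimate: float
    lm_se: float
    lm_t: float
    lm_p: float


def compute_increase_rate(
    net: SpeciesNetwork,
    cls: OxygenClassification,
    basis: str = "enzyme",
    unclassified: str = "exclude",
) -> ExpansionResult:
    """Compute a species' oxic/anoxic increase rate on one basis.

    ``unclassified='exclude'`` (default) counts only items present in the
    oxic or anoxic global lists; ``'count_in_total'`` counts every item of
    the species network in the numerator.  A species without anoxic items
    has an undefined rate and is flagged rather than given a value.
    """
    if basis == "enzyme":
        items, oxic, anoxic = net.enzymes, cls.oxic_enzymes, cls.anoxic_enzymes
    elif basis == "metabolite":
        items, oxic, anoxic = net.metabolites, cls.oxic_metabolites, cls.anoxic_metabolites
    else:
        raise ValidationError(f"unknown basis {basis!r}")
    if oxic & anoxic:
        raise ValidationError("classification sets must be disjoint")
    if unclassified == "exclude":
        n_total = len(items & (oxic | anoxic))
    elif unclassified == "count_in_total":
        n_total = len(items)
    else:
        raise ValidationError(f"unknown unclassified mode {unclassified!r}")
    n_anoxic = len(items & anoxic)
    if n_anoxic == 0:
        return ExpansionResult(net.organism_id, basis, n_total, 0, math.nan, undefined=True)
    return ExpansionResult(net.organism_id, basis, n_total, n_anoxic, n_total / n_anoxic)


def wmw_two_sided_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-tailed WMW p; exact null when the pooled sample is small and
    tie-free, otherwise normal approximation with tie and continuity
    correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    exact = len(pooled) <= EXACT_WMW_LIMIT and len(np.unique(pooled)) == len(pooled)
    method = "exact" if exact else "asymptotic"
    return float(st.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def compare_groups(
    rates_a: Iterable[float],
    rates_b: Iterable[float],
    group_a_label: str = "aerobes",
    group_b_label: str = "anaerobes",
) -> GroupComparison:
    """Compare two groups of increase rates.

    Reports the two-tailed WMW p and an OLS fit of rate on the group
    indicator (1 for group a); for a binary regressor the slope equals the
    difference of group means and the t test has ``n_a + n_b - 2`` degrees
    of freedom.
    """
    a = np.asarray([r for r in rates_a if math.isfinite(r)], dtype=float)
    b = np.asarray([r for r in rates_b if math.isfinite(r)], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 finite values")
    y = np.concatenate([a, b])
    x = sm.add_constant(np.concatenate([np.ones(len(a)), np.zeros(len(b))]))
    fit = sm.OLS(y, x).fit()
    return GroupComparison(
        group_a_label=group_a_label,
        group_b_label=group_b_label,
        n_a=len(a),
        n_b=len(b),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        wmw_p=wmw_two_sided_p(a, b),
        lm_estimate=float(fit.params[1]),
        lm_se=float(fit.bse[1]),
        lm_t=float(fit.tvalues[1]),
        lm_p=float(fit.pvalues[1]),
    )
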