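"""Two-population comparison machinery for descriptor distributions.

The comparison of two compound populations follows a decision tree:
Student's t test when both samples pass a Shapiro normality test and a
two-sided F ratio test finds equivalent variances, otherwise the
nonparametric Mann-Whitney-Wilcoxon test.  Multi-group comparisons use a
Kruskal-Wallis omnibus test followed by pairwise Mann-Whitney-Wilcoxon
post hocs.  All tests are two-tailed; the working significance level is
0.05 for ligand descriptors and 1e-4 for pocket descriptors.  Raw p-values
are reported by default (no multiplicity correction), with Holm correction
available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

MIN_GROUP_SIZE = 5
#: Classical validity cap of the Shapiro test; larger samples are tested on
#: a fixed-seed subsample of this size.
SHAPIRO_CAP = 5000


@dataclass
class ComparisonResult:
    test_used: str  # "Student" or "Mann-Whitney-Wilcoxon"
    p_value: float
    direction: int  # sign of (location of a - location of b)

    @property
    def star_level(self) -> str:
        return stars(self.p_value)


def stars(p: float) -> str:
    """Significance stars: *** below 0.001, ** below 0.01, * below 0.05."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _shapiro_normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:  # constant sample: degenerate, not normal
        return False
    if len(x) > SHAPIRO_CAP:
        x = np.random.default_rng(0).choice(x, size=SHAPIRO_CAP, replace=False)
    return sps.shapiro(x).pvalue > alpha


def _f_test_equal_var(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F ratio test for variance equality."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    p = sps.f.cdf(f, len(a) - 1, len(b) - 1)
    return 2.0 * min(p, 1.0 - p)


def _mww(a: np.ndarray, b: np.ndarray) -> float:
    # exact p only for small tie-free samples; normal approximation with
    # tie correction otherwise
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 50 and len(b) <= 50 and not ties) else "asymptotic"
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def compare_two(a, b, alpha: float = 0.05) -> ComparisonResult:
    """Compare two samples by the parametric-first decision tree.

    Student's t test is used iff both samples are Shapiro-normal at
    ``alpha`` and a two-sided F test accepts variance equality at ``alpha``;
    otherwise Mann-Whitney-Wilcoxon.  Direction is the sign of the mean
    (Student) or median (MWW) difference, a - b.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < MIN_GROUP_SIZE or len(b) < MIN_GROUP_SIZE:
        raise ValueError(
            f"each sample needs >= {MIN_GROUP_SIZE} values "
            f"(got {len(a)} and {len(b)})"
        )
    parametric = (
        _shapiro_normal(a, alpha)
        and _shapiro_normal(b, alpha)
        and _f_test_equal_var(a, b) > alpha
    )
    if parametric:
        p = float(sps.ttest_ind(a, b, equal_var=True).pvalue)
        diff = float(np.mean(a) - np.mean(b))
        test = "Student"
    else:
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            # all values tied across both samples: no evidence of difference
            return ComparisonResult("Mann-Whitney-Wilcoxon", 1.0, 0)
        p = _mww(a, b)
        diff = float(np.median(a) - np.median(b))
        test = "Mann-Whitney-Wilcoxon"
    return ComparisonResult(test, p, int(np.sign(diff)))


@dataclass
class PosthocResult:
    omnibus_p: float
    labels: list
    pairwise: pd.DataFrame  # symmetric matrix of MWW p-values
    degenerate: bool = False

    def significant_pairs(self, alpha: float) -> list[tuple]:
        out = []
        for i, la in enumerate(self.labels):
            for lb in self.labels[i + 1 :]:
                if self.pairwise.loc[la, lb] < alpha:
                    out.append((la, lb))
        return out


def anova_posthoc(
    groups: dict[str, np.ndarray] | list[np.ndarray],
    alpha: float = 0.05,
    holm: bool = False,
) -> PosthocResult:
    """Kruskal-Wallis omnibus + full pairwise MWW post hoc matrix.

    No multiplicity correction by default; ``holm=True`` applies Holm's
    step-down correction to the pairwise p-values.
    """
    if isinstance(groups, dict):
        labels = list(groups)
        samples = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        labels = list(range(len(groups)))
        samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for lab, s in zip(labels, samples):
        if len(s) < MIN_GROUP_SIZE:
            raise ValueError(f"group {lab!r} smaller than {MIN_GROUP_SIZE}")

    pooled = np.concatenate(samples)
    degenerate = np.ptp(pooled) == 0
    if degenerate:
        omnibus_p = 1.0
        logger.warning("all values tied across all groups; omnibus p set to 1")
    else:
        omnibus_p = float(sps.kruskal(*samples).pvalue)

    k = len(samples)
    pmat = np.ones((k, k))
    pvals, pairs = [], []
    for i in range(k):
        for j in range(i + 1, k):
            if degenerate:
                p = 1.0
            else:
                p = _mww(samples[i], samples[j])
            pvals.append(p)
            pairs.append((i, j))
    if holm and pvals:
        from statsmodels.stats.multitest import multipletests

        pvals = list(multipletests(pvals, method="holm")[1])
    for (i, j), p in zip(pairs, pvals):
        pmat[i, j] = pmat[j, i] = p
    pairwise = pd.DataFrame(pmat, index=labels, columns=labels)
    return PosthocResult(omnibus_p, labels, pairwise, degenerate)


def count_significant(
    collection: pd.DataFrame,
    ippi_targets: list[str],
    reference_sets: list[str],
    descriptors: list[str],
    alpha: float = 0.05,
    target_col: str = "target",
    dataset_col: str = "dataset",
) -> pd.DataFrame:
    """Count, per (PPI target, descriptor), the reference datasets that differ.

    For each PPI-target family with at least :data:`MIN_GROUP_SIZE`
    compounds, each descriptor distribution is compared (decision tree,
    ``alpha``) with the same descriptor in every reference dataset; the
    cell value is the number of reference datasets found significantly
    different.  Smaller families are dropped and logged, not an error.
    """
    rows = {}
    for t in ippi_targets:
        members = collection[collection[target_col] == t]
        if len(members) < MIN_GROUP_SIZE:
            logger.info("target %r dropped: only %d compounds", t, len(members))
            continue
        counts = {}
        for d in descriptors:
            n_sig = 0
            for r in reference_sets:
                ref = collection.loc[collection[dataset_col] == r, d].to_numpy()
                res = compare_two(members[d].to_numpy(), ref, alpha)
                if res.p_value < alpha:
                    n_sig += 1
            counts[d] = n_sig
        rows[t] = counts
    table = pd.DataFrame.from_dict(rows, orient="index", columns=descriptors)
    table.index.name = target_col
    return table


def significance_histogram(count_table: pd.DataFrame, n_reference: int) -> pd.DataFrame:
    """Per descriptor, the number of targets at each count of significantly
    different reference datasets (0..n_reference)."""
    hist = {
        d: count_table[d].value_counts().reindex(range(n_reference + 1), fill_value=0)
        for d in count_table.columns
    }
    out = pd.DataFrame(hist)
    out.index.name = "n_significant_references"
    return out
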