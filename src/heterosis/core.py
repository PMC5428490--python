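"""Eight-class hybrid/parent expression classification and MPV testing.

For each gene the two parental replicate-group means are ordered into a low
parent (LP) and a high parent (HP), and the hybrid mean H is compared with
each by fold change (FC).  Two means are "different" when the larger exceeds
the smaller by at least a fold threshold f (default 2); otherwise they are
"equal".  The pairwise relations (LP vs H, HP vs H, LP vs HP) determine
exactly one of eight classes:

    1  LP < H < HP    partial dominance, hybrid intermediate
    2  LP < H = HP    high-parent dominance
    3  LP = H < HP    low-parent dominance
    4  LP = H = HP    no differential expression
    5  LP < HP < H    overdominance (above high parent)
    6  LP = HP < H    overdominance, parents equal
    7  H < LP < HP    underdominance (below low parent)
    8  H < LP = HP    underdominance, parents equal

Independently of the class, a gene is called *non-additive* when hybrid
replicate expression differs significantly from the mid-parent value
MPV = (parentA + parentB)/2 — an unequal-variance location test of the
hybrid replicates against per-replicate pseudo-MPV values (parents equally
replicated) or against the scalar MPV otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import (
    ConfigError,
    InsufficientReplicationError,
    InternalConsistencyError,
)
from .io import TrioExpressionSet


class Relation(str, Enum):
    LESS = "less"
    EQUAL = "equal"
    GREATER = "greater"


@dataclass(frozen=True)
class RelationConfig:
    """Thresholds governing fold-change relations and the MPV test.

    fold_threshold : ratio at or above which two means are called different
        (the "at least two-fold change" rule).
    pseudocount : added to both means before taking the ratio, stabilizing
        genes near zero expression. Set to 0 for exact-ratio arithmetic.
    alpha : significance level of the non-additivity call.
    """

    fold_threshold: float = 2.0
    pseudocount: float = 1.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.fold_threshold > 1:
            raise ConfigError(f"fold_threshold must be > 1, got {self.fold_threshold}")
        if self.pseudocount < 0:
            raise ConfigError(f"pseudocount must be >= 0, got {self.pseudocount}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class GeneClassification:
    """Per-gene classification record."""

    gene_id: str
    mean_pA: float
    mean_pB: float
    mean_H: float
    lp_parent: str
    mean_LP: float
    mean_HP: float
    class_id: int
    fc_H_LP: float
    fc_HP_H: float
    fc_HP_LP: float
    mpv: float
    p_nonadditive: float
    nonadditive: bool


@dataclass
class ClassSummary:
    """Per-class total and non-additive gene counts for one tissue/stage."""

    tissue: str
    stage: str
    total_count: dict[int, int]
    nonadditive_count: dict[int, int]

    def __post_init__(self) -> None:
        for cid in range(1, 9):
            self.total_count.setdefault(cid, 0)
            self.nonadditive_count.setdefault(cid, 0)
        for cid in range(1, 9):
            if self.nonadditive_count[cid] > self.total_count[cid]:
                raise ConfigError(
                    f"class {cid}: non-additive count exceeds total"
                )

    @property
    def total_genes(self) -> int:
        return sum(self.total_count[c] for c in range(1, 9))

    @property
    def nonadditive_total(self) -> int:
        return sum(self.nonadditive_count[c] for c in range(1, 9))


def fold_change(a: float, b: float, pseudocount: float = 0.0) -> float:
    """Symmetric fold change max(a+c, b+c)/min(a+c, b+c); 1.0 when both zero."""
    if a < 0 or b < 0:
        raise ValueError("fold_change expects non-negative inputs")
    hi = max(a, b) + pseudocount
    lo = min(a, b) + pseudocount
    if hi == 0.0:
        return 1.0
    if lo == 0.0:
        return math.inf
    return hi / lo


def relation(x: float, y: float, cfg: RelationConfig | None = None) -> Relation:
    """Relation of ``y`` to ``x``: greater / less when FC >= threshold, else equal."""
    cfg = cfg or RelationConfig()
    c, f = cfg.pseudocount, cfg.fold_threshold
    xc, yc = x + c, y + c
    if xc == yc:  # covers both-zero with c=0, where the ratio is defined as 1
        return Relation.EQUAL
    if yc >= f * xc:
        return Relation.GREATER
    if xc >= f * yc:
        return Relation.LESS
    return Relation.EQUAL


def assign_lp_hp(mean_pA: float, mean_pB: float) -> tuple[str, float, float]:
    """Order the parents into (lp_parent, mean_LP, mean_HP); ties label parentA LP."""
    if mean_pB < mean_pA:
        return "parentB", mean_pB, mean_pA
    return "parentA", mean_pA, mean_pB


_CLASS_BY_RELATIONS = {
    (Relation.GREATER, Relation.LESS): 1,
    (Relation.GREATER, Relation.EQUAL): 2,
    (Relation.EQUAL, Relation.LESS): 3,
    (Relation.EQUAL, Relation.EQUAL): 4,
}


def classify_gene(
    mean_pA: float,
    mean_pB: float,
    mean_H: float,
    cfg: RelationConfig | None = None,
) -> int:
    """Assign one of the eight expression classes from the three group means."""
    cfg = cfg or RelationConfig()
    _, lp, hp = assign_lp_hp(mean_pA, mean_pB)
    r_h_lp = relation(lp, mean_H, cfg)   # H relative to LP
    r_h_hp = relation(hp, mean_H, cfg)   # H relative to HP
    key = (r_h_lp, r_h_hp)
    if key in _CLASS_BY_RELATIONS:
        return _CLASS_BY_RELATIONS[key]
    if key == (Relation.GREATER, Relation.GREATER):
        r_p = relation(lp, hp, cfg)
        return 5 if r_p is Relation.GREATER else 6
    if key == (Relation.LESS, Relation.LESS):
        r_p = relation(lp, hp, cfg)
        return 7 if r_p is Relation.GREATER else 8
    # (less, equal) and (equal, greater) are impossible when LP <= HP:
    # the fold change of H against HP can never exceed that against LP.
    raise InternalConsistencyError(
        f"impossible relation pair {key} for LP={lp}, HP={hp}, H={mean_H}"
    )


def mpv(mean_pA: float, mean_pB: float) -> float:
    """Mid-parent value, (parentA + parentB)/2."""
    return (mean_pA + mean_pB) / 2.0


def nonadditivity_test(
    hybrid_reps: Sequence[float],
    pA_reps: Sequence[float],
    pB_reps: Sequence[float],
    cfg: RelationConfig | None = None,
) -> tuple[float, bool]:
    """Test whether hybrid expression departs from the mid-parent value.

    With equally replicated parents, pseudo-MPV replicates
    m_i = (pA_i + pB_i)/2 are formed by replicate index and compared with the
    hybrid replicates by a two-sample unequal-variance (Welch) t-test; with
    unequal parent replication a one-sample t-test of the hybrid replicates
    against the scalar MPV of the parent means is used.

    Returns (p_value, p_value < alpha). Zero variance everywhere with equal
    means yields p = 1; zero variance with unequal means yields p = 0.
    """
    cfg = cfg or RelationConfig()
    h = np.asarray(hybrid_reps, dtype=float)
    a = np.asarray(pA_reps, dtype=float)
    b = np.asarray(pB_reps, dtype=float)
    if h.size < 2:
        raise InsufficientReplicationError(
            f"need >= 2 hybrid replicates, got {h.size}"
        )
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicationError(
            f"need >= 2 replicates per parent, got {a.size} and {b.size}"
        )
    if a.size == b.size:
        m = (a + b) / 2.0
        if h.std(ddof=1) == 0.0 and m.std(ddof=1) == 0.0:
            p = 1.0 if h.mean() == m.mean() else 0.0
        else:
            p = float(stats.ttest_ind(h, m, equal_var=False).pvalue)
    else:
        target = mpv(a.mean(), b.mean())
        if h.std(ddof=1) == 0.0:
            p = 1.0 if h.mean() == target else 0.0
        else:
            p = float(stats.ttest_1samp(h, popmean=target).pvalue)
    return p, bool(p < cfg.alpha)


def _nonadditivity_pvalues(xs: TrioExpressionSet) -> np.ndarray:
    """Vectorized per-gene MPV test over a whole expression set."""
    h = xs.group_values("hybrid")
    a = xs.group_values("parentA")
    b = xs.group_values("parentB")
    if h.shape[1] < 2 or a.shape[1] < 2 or b.shape[1] < 2:
        raise InsufficientReplicationError(
            "non-additivity testing needs >= 2 replicates in every group"
        )
    import warnings

    if a.shape[1] == b.shape[1]:
        m = (a + b) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = stats.ttest_ind(h, m, axis=1, equal_var=False).pvalue
        degenerate = (h.std(axis=1, ddof=1) == 0) & (m.std(axis=1, ddof=1) == 0)
        equal_means = h.mean(axis=1) == m.mean(axis=1)
    else:
        target = (a.mean(axis=1) + b.mean(axis=1)) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = stats.ttest_1samp(h, popmean=target, axis=1).pvalue
        degenerate = h.std(axis=1, ddof=1) == 0
        equal_means = h.mean(axis=1) == target
    p = np.asarray(p, dtype=float)
    p[degenerate & equal_means] = 1.0
    p[degenerate & ~equal_means] = 0.0
    # residual NaNs (one sample constant, the other not, means equal) -> no call
    p[np.isnan(p)] = 1.0
    return p


def classify_transcriptome(
    xs: TrioExpressionSet,
    cfg: RelationConfig | None = None,
    fdr: bool = False,
) -> tuple[list[GeneClassification], ClassSummary]:
    """Classify every gene of a trio expression set and tally the classes.

    ``fdr=True`` applies Benjamini-Hochberg correction across genes before
    thresholding the non-additivity call at ``cfg.alpha`` (off by default).
    """
    cfg = cfg or RelationConfig()
    mean_a = xs.group_means("parentA")
    mean_b = xs.group_means("parentB")
    mean_h = xs.group_means("hybrid")
    pvals = _nonadditivity_pvalues(xs)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        pvals_call = multipletests(pvals, method="fdr_bh")[1]
    else:
        pvals_call = pvals

    records: list[GeneClassification] = []
    totals = {c: 0 for c in range(1, 9)}
    na_counts = {c: 0 for c in range(1, 9)}
    c = cfg.pseudocount
    for i, gene in enumerate(xs.gene_ids):
        lp_parent, lp, hp = assign_lp_hp(float(mean_a[i]), float(mean_b[i]))
        cid = classify_gene(float(mean_a[i]), float(mean_b[i]), float(mean_h[i]), cfg)
        na = bool(pvals_call[i] < cfg.alpha)
        records.append(
            GeneClassification(
                gene_id=gene,
                mean_pA=float(mean_a[i]),
                mean_pB=float(mean_b[i]),
                mean_H=float(mean_h[i]),
                lp_parent=lp_parent,
                mean_LP=lp,
                mean_HP=hp,
                class_id=cid,
                fc_H_LP=fold_change(lp, float(mean_h[i]), c),
                fc_HP_H=fold_change(hp, float(mean_h[i]), c),
                fc_HP_LP=fold_change(hp, lp, c),
                mpv=mpv(float(mean_a[i]), float(mean_b[i])),
                p_nonadditive=float(pvals[i]),
                nonadditive=na,
            )
        )
        totals[cid] += 1
        if na:
            na_counts[cid] += 1
    summary = ClassSummary(
        tissue=xs.tissue,
        stage=xs.stage,
        total_count=totals,
        nonadditive_count=na_counts,
    )
    return records, summary


def class_union_counts(summary: ClassSummary, classes: Iterable[int]) -> int:
    """Total genes across a union of classes (e.g. {2,5,6}: hybrid above a parent)."""
    classes = set(classes)
    bad = classes - set(range(1, 9))
    if bad:
        raise ValueError(f"class ids outside 1-8: {sorted(bad)}")
    return sum(summary.total_count[c] for c in classes)


def updown_ratio(
    xs: TrioExpressionSet,
    numerator_group: str,
    denominator_group: str,
    gene_set: Iterable[str] | None = None,
    cfg: RelationConfig | None = None,
) -> tuple[int, int, float]:
    """Count up-/down-regulated genes between two groups and their ratio.

    A gene is *up* when the numerator-group mean exceeds the denominator-group
    mean by at least the fold threshold, *down* for the converse. The ratio
    n_up/n_down is NaN when no gene is down.
    """
    cfg = cfg or RelationConfig()
    num = xs.group_means(numerator_group)
    den = xs.group_means(denominator_group)
    if gene_set is None:
        idx = range(len(xs.gene_ids))
    else:
        gene_set = set(gene_set)
        stray = gene_set - set(xs.gene_ids)
        if stray:
            raise ValueError(f"genes not in expression set: {sorted(stray)[:5]}")
        index = xs.gene_index()
        idx = [index[g] for g in xs.gene_ids if g in gene_set]
    n_up = n_down = 0
    for i in idx:
        rel = relation(float(den[i]), float(num[i]), cfg)
        if rel is Relation.GREATER:
            n_up += 1
        elif rel is Relation.LESS:
            n_down += 1
    ratio = n_up / n_down if n_down > 0 else math.nan
    return n_up, n_down, ratio
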