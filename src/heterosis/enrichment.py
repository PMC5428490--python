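"""Over-representation testing of gene sets among flagged genes.

Given a selected gene set (typically the non-additive genes of one tissue)
and a pathway catalog over the classified-gene universe, each pathway is
tested with a one-sided hypergeometric tail P(X >= k) and the p-values are
Benjamini-Hochberg adjusted across pathways.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import PathwayCatalog


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_name: str
    universe_size: int      # N
    pathway_size: int       # K
    selected_size: int      # n
    overlap: int            # k
    p_value: float
    q_value: float


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the pathway size, n the selection size and k
    the observed overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent sizes K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    selected: Iterable[str],
    catalog: PathwayCatalog,
    fdr_method: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """Test every catalog pathway for over-representation in ``selected``.

    Results are sorted by ascending p-value, ties broken by pathway name.
    """
    selected = frozenset(selected)
    stray = selected - catalog.universe
    if stray:
        raise ValueError(
            f"selected gene {sorted(stray)[0]!r} is not in the catalog universe"
        )
    N = len(catalog.universe)
    n = len(selected)
    names = sorted(catalog.pathways)
    raw = []
    for name in names:
        members = catalog.pathways[name]
        K = len(members)
        k = len(members & selected)
        raw.append((name, K, k, hypergeometric_tail(k, K, n, N)))
    if not raw:
        return []
    qvals = multipletests([r[3] for r in raw], method=fdr_method)[1]
    results = [
        EnrichmentResult(
            pathway_name=name,
            universe_size=N,
            pathway_size=K,
            selected_size=n,
            overlap=k,
            p_value=p,
            q_value=float(q),
        )
        for (name, K, k, p), q in zip(raw, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.pathway_name))
    return results
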