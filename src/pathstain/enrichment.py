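"""Module enrichment for uploaded gene lists (the "functional analysis" step).

For each module of the map the upper-tail hypergeometric test asks: drawing
``n`` symbols (the uploaded list restricted to the map) without replacement
from a universe of ``N`` symbols (everything on the map), how surprising is
an overlap of at least ``k`` with the module's ``K`` symbols?

    P(X >= k) = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

The universe is deliberately the map, not the genome: the question answered
is "which module *of this map* is enriched", guiding which region to stain
or zoom into next.  Raw p-values are reported alongside Benjamini-Hochberg
q-values across the map's modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .map_model import NetworkMap, canonical_symbol

__all__ = ["EnrichmentRow", "hypergeom_tail", "module_enrichment", "enrichment_to_tsv"]


@dataclass(frozen=True)
class EnrichmentRow:
    module_id: str
    name: str
    N: int  # universe: distinct symbols on the map
    K: int  # distinct symbols in the module
    n: int  # distinct uploaded symbols found on the map
    k: int  # overlap of the list with the module
    p_value: float
    q_value: float


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Delegates to scipy's survival function, which works in log space, so the
    result is stable for large counts.  ``k = 0`` is exactly 1.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if not isinstance(v, (int, np.integer)):
            raise ValueError(f"{name} must be an integer, got {v!r}")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K <= N and 0 <= n <= N; got N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n)={min(K, n)}; got k={k}")
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(1.0, max(p, 5e-324))


def _bh_adjust(pvalues: list[float]) -> list[float]:
    # Benjamini-Hochberg step-up: q_(i) = min_{j >= i} p_(j) * m / j, capped at 1
    m = len(pvalues)
    order = np.argsort(pvalues, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, pvalues[idx] * m / rank)
        q[idx] = running
    return q.tolist()


def module_enrichment(nmap: NetworkMap, gene_list: list[str]) -> list[EnrichmentRow]:
    """Hypergeometric enrichment of a gene list against every map module.

    Symbols are counted once per module regardless of how many entities
    (aliases, complexes) carry them; uploaded symbols absent from the map are
    dropped from ``n``.  Rows are sorted by ascending p-value (module id
    breaks ties).  A list disjoint from the map is not an error: every row
    then has k = 0 and p = 1.
    """
    if not nmap.modules:
        raise ValueError("map has no modules to test")
    universe = nmap.all_symbols()
    N = len(universe)
    uploaded = {canonical_symbol(s) for s in gene_list} - {""}
    on_map = uploaded & universe
    n = len(on_map)

    by_id = {e.entity_id: e for e in nmap.entities}
    rows = []
    for mod in nmap.modules:
        mod_symbols: set[str] = set()
        for eid in mod.member_ids:
            mod_symbols.update(by_id[eid].hugo_symbols)
        K = len(mod_symbols)
        k = len(on_map & mod_symbols)
        p = hypergeom_tail(N, K, n, k)
        rows.append((mod.module_id, mod.name, K, k, p))

    qvals = _bh_adjust([r[4] for r in rows])
    out = [
        EnrichmentRow(mid, name, N, K, n, k, p, q)
        for (mid, name, K, k, p), q in zip(rows, qvals)
    ]
    out.sort(key=lambda r: (r.p_value, r.module_id))
    return out


def enrichment_to_tsv(rows: list[EnrichmentRow]) -> str:
    lines = ["module_id\tname\tN\tK\tn\tk\tp_value\tq_value"]
    for r in rows:
        lines.append(
            f"{r.module_id}\t{r.name}\t{r.N}\t{r.K}\t{r.n}\t{r.k}"
            f"\t{r.p_value:.6g}\t{r.q_value:.6g}"
        )
    return "\n".join(lines) + "\n"
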