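"""Hypergeometric pathway enrichment of a target set.

For a universe of N genes (the union of all pathway members) containing K
drug targets, a pathway of n genes holding k targets is scored by the
upper-tail probability

    P = P(X >= k),  X ~ Hypergeometric(N, K, n)

i.e. the chance that at least k targets land in the pathway under uniform
draws.  A small P flags the pathway as enriched.  Raw p-values with the
alpha = 0.01 cut reproduce the study convention; Benjamini-Hochberg
q-values are reported alongside for users who want a corrected view.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .netio import GeneSetCollection

__all__ = [
    "EnrichmentResult",
    "hypergeom_pmf",
    "hypergeom_pvalue",
    "enrich_targets",
]

DEFAULT_ALPHA = 0.01


def _check_params(N: int, K: int, n: int) -> None:
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")


def hypergeom_pmf(N: int, K: int, n: int, i: int) -> float:
    """P(X = i) for X ~ Hypergeometric(N, K, n).

    C(K,i) * C(N-K, n-i) / C(N,n); zero outside the support
    [max(0, n-N+K), min(n, K)].  Evaluated through scipy's log-space
    implementation, which is overflow-safe at interactome scale.
    """
    _check_params(N, K, n)
    if i < max(0, n - (N - K)) or i > min(n, K):
        return 0.0
    return float(stats.hypergeom.pmf(i, N, K, n))


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Computed as the survival function at k-1 (a direct stable tail sum),
    not as 1 minus the lower CDF, which loses precision for small P.
    P = 1 exactly when k <= max(0, n-N+K) (in particular k = 0).
    """
    _check_params(N, K, n)
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if k <= max(0, n - (N - K)):
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-pathway enrichment table plus the shared counts.

    ``rows`` columns: pathway_id, name, n (pathway size), k (targets in the
    pathway), p_value, q_value (Benjamini-Hochberg), significant (raw
    p < alpha); sorted ascending by p_value, ties by pathway_id.
    """

    rows: pd.DataFrame
    N: int
    K: int
    alpha: float
    missing_targets: tuple[str, ...]

    @property
    def significant_ids(self) -> list[str]:
        return self.rows.loc[self.rows["significant"], "pathway_id"].tolist()

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.6g")


def enrich_targets(
    targets: Iterable[str],
    pathways: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
) -> EnrichmentResult:
    """Score every pathway for over-representation of ``targets``.

    The universe N is the union of pathway members; targets outside the
    universe are excluded from K and listed in ``missing_targets``.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    targets = {t.strip().upper() for t in targets}
    universe = pathways.universe
    in_univ = targets & universe
    missing = tuple(sorted(targets - universe))
    N, K = len(universe), len(in_univ)
    if K == 0:
        raise ValueError("no targets in pathway universe")

    recs = []
    for pid in sorted(pathways.sets):
        name, members = pathways.sets[pid]
        n, k = len(members), len(in_univ & members)
        recs.append((pid, name, n, k, hypergeom_pvalue(N, K, n, k)))
    df = pd.DataFrame(recs, columns=["pathway_id", "name", "n", "k", "p_value"])
    df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    df["significant"] = df["p_value"] < alpha
    df = df.sort_values(["p_value", "pathway_id"], kind="mergesort").reset_index(
        drop=True
    )
    return EnrichmentResult(df, N=N, K=K, alpha=alpha, missing_targets=missing)
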