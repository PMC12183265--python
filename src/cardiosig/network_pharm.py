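"""Network-pharmacology utilities: target-set assembly, STRING-dialect
network loading, node centralities (degree, betweenness, closeness and
maximal clique centrality) and hypergeometric gene-set enrichment.

Gene symbols are matched after uppercasing throughout.  STRING combined
scores stay on the 0–1000 integer scale; the usual "highest confidence"
cut of 0.9 corresponds to ``min_score=900``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

CENTRALITY_METRICS = ("degree", "betweenness", "closeness", "mcc")


@dataclass
class ScoredTargetList:
    """Gene symbols with non-negative relevance scores from one source."""

    source: str
    entries: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        up = {}
        for sym, score in self.entries.items():
            key = str(sym).strip().upper()
            if score < 0:
                raise ValueError(f"{self.source}: negative score for {key}")
            if key in up:
                raise ValueError(f"{self.source}: duplicate symbol {key}")
            up[key] = float(score)
        self.entries = up

    @classmethod
    def from_csv(cls, path: str | Path, source: str | None = None) -> "ScoredTargetList":
        """Two-column CSV (symbol, score); header optional."""
        entries: dict[str, float] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or not row[0].strip():
                    continue
                try:
                    score = float(row[1])
                except (IndexError, ValueError):
                    continue  # header or malformed
                entries[row[0]] = score
        return cls(source=source or Path(path).stem, entries=entries)

    def symbols(self) -> set[str]:
        return set(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def merge_disease_targets(
    lists: Sequence[ScoredTargetList], score_floor: float = 10.0
) -> ScoredTargetList:
    """Merge per-keyword disease target lists into one deduplicated list.

    Entries below ``score_floor`` are dropped; the surviving entries are
    pooled, the pooled median score computed, entries strictly below that
    median dropped, and duplicates collapsed keeping the maximum score.
    """
    if not lists:
        raise ValueError("at least one target list is required")
    pooled: list[tuple[str, float]] = []
    for lst in lists:
        pooled.extend(
            (sym, score) for sym, score in lst.entries.items()
            if score >= score_floor
        )
    if not pooled:
        import warnings

        warnings.warn("no targets survive the score floor; result is empty")
        return ScoredTargetList(source="merged", entries={})
    median = float(np.median([score for _, score in pooled]))
    merged: dict[str, float] = {}
    for sym, score in pooled:
        if score < median:
            continue
        merged[sym] = max(score, merged.get(sym, score))
    return ScoredTargetList(source="merged", entries=merged)


def intersect_targets(
    set_a: Iterable[str], set_b: Iterable[str]
) -> tuple[list[str], tuple[int, int, int]]:
    """Case-normalized intersection plus Venn counts (A only, shared, B only)."""
    a = {str(s).strip().upper() for s in set_a}
    b = {str(s).strip().upper() for s in set_b}
    shared = sorted(a & b)
    return shared, (len(a - b), len(shared), len(b - a))


# ---------------------------------------------------------------------------
# STRING-dialect interaction networks

_NODE_COLS = (("node1", "node2"), ("#node1", "node2"), ("protein1", "protein2"))


def load_string_tsv(path: str | Path, min_score: int = 900) -> nx.Graph:
    """Load a STRING-style TSV edge list into an undirected scored graph.

    Edges with combined score >= ``min_score`` are kept; duplicates (either
    direction) collapse to the maximum score; self-loops are dropped and
    counted in ``G.graph["n_self_loops"]``.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for c1, c2 in _NODE_COLS:
            if c1 in header and c2 in header:
                break
        else:
            raise ValueError(f"{path.name}: no recognised node columns in {header}")
        score_col = next(
            (c for c in ("combined_score", "score") if c in header), None
        )
        if score_col is None:
            raise ValueError(f"{path.name}: no combined_score column in {header}")
        g = nx.Graph()
        n_self = 0
        for lineno, row in enumerate(reader, start=2):
            try:
                score = float(row[score_col])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path.name}:{lineno}: malformed score {row.get(score_col)!r}"
                ) from None
            if not 0 <= score <= 1000:
                raise ValueError(
                    f"{path.name}:{lineno}: score {score} outside [0, 1000]"
                )
            u = str(row[c1]).strip().upper()
            v = str(row[c2]).strip().upper()
            if u == v:
                n_self += 1
                continue
            if score < min_score:
                continue
            if g.has_edge(u, v):
                g[u][v]["score"] = max(g[u][v]["score"], score)
            else:
                g.add_edge(u, v, score=score)
    g.graph["n_self_loops"] = n_self
    return g


# ---------------------------------------------------------------------------
# centralities

def mcc_scores(g: nx.Graph) -> dict[str, int]:
    """Maximal clique centrality: for each node, the sum of (|C| − 1)! over
    the maximal cliques C containing it.  An isolated node sits in the
    single maximal clique {v}, so MCC >= 1 everywhere."""
    scores = {v: 0 for v in g.nodes}
    for clique in nx.find_cliques(g):
        w = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    return scores


def centralities(g: nx.Graph) -> pd.DataFrame:
    """Per-node degree, betweenness, closeness and MCC.

    Betweenness is the unnormalized undirected count (ordered source–target
    pairs divided by two); closeness uses the Wasserman–Faust
    within-component form scaled by (reachable − 1)/(n − 1), 0 for
    isolates.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("network is empty")
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=False)
    clo = nx.closeness_centrality(g, wf_improved=True)
    mcc = mcc_scores(g)
    df = pd.DataFrame({
        "degree": pd.Series(deg),
        "betweenness": pd.Series(btw),
        "closeness": pd.Series(clo),
        "mcc": pd.Series(mcc),
    })
    return df.loc[sorted(df.index, key=str)]


def top_hubs(scores: pd.DataFrame, metric: str, k: int = 10) -> list[str]:
    """Top-k nodes by a centrality metric (value desc, symbol asc)."""
    if metric not in CENTRALITY_METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {CENTRALITY_METRICS}")
    ranked = sorted(
        scores[metric].items(), key=lambda kv: (-float(kv[1]), str(kv[0]))
    )
    return [sym for sym, _ in ranked[: min(k, len(ranked))]]


# ---------------------------------------------------------------------------
# gene-set enrichment

@dataclass
class EnrichmentResult:
    term: str
    description: str
    k: int  # overlap
    K: int  # term size within universe
    n: int  # query size within universe
    M: int  # universe size
    p_value: float
    q_value: float
    significant: bool


def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    """Read a GMT gene-set file: term, description, member symbols."""
    sets: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            genes = {g.strip().upper() for g in parts[2:] if g.strip()}
            sets[parts[0]] = (parts[1], genes)
    return sets


def enrich(
    query: Iterable[str],
    gene_sets: Mapping[str, tuple[str, set[str]]],
    universe: Iterable[str],
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation test per gene set.

    Query symbols outside the universe are dropped (with a warning); each
    gene set is intersected with the universe first.  P(X >= k) with
    population M, K successes, n draws; Benjamini–Hochberg across all
    terms; results sorted by p ascending (ties by term).
    """
    uni = {str(s).strip().upper() for s in universe}
    if not uni:
        raise ValueError("universe is empty")
    q = {str(s).strip().upper() for s in query}
    dropped = q - uni
    if dropped:
        import warnings

        warnings.warn(f"{len(dropped)} query symbols outside universe dropped")
    q &= uni
    M, n = len(uni), len(q)
    raw = []
    for term, (desc, genes) in gene_sets.items():
        members = genes & uni
        K = len(members)
        k = len(members & q)
        p = float(hypergeom.sf(k - 1, M, K, n))
        raw.append((term, desc, k, K, p))
    if not raw:
        return []
    pvals = np.clip([r[4] for r in raw], 0.0, 1.0)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(
            term=term, description=desc, k=k, K=K, n=n, M=M,
            p_value=p, q_value=float(qv), significant=p < alpha,
        )
        for (term, desc, k, K, p), qv in zip(raw, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results
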