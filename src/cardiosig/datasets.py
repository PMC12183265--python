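"""Synthetic network-pharmacology inputs with planted structure.

The live services behind the published target lists (GeneCards,
PharmMapper, Swiss Target Prediction, STRING, Metascape) cannot be queried
reproducibly, so these builders emit synthetic stand-ins with the same
shapes and known ground truth: target lists of the published sizes with a
planted intersection, a STRING-dialect edge list with planted hub wiring,
and small GMT collections with planted enriched terms.
"""

from __future__ import annotations

import numpy as np

from cardiosig.network_pharm import ScoredTargetList
from cardiosig.reference_tables import HUB_TARGETS


def _symbols(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(n)]


def make_target_lists(
    n_drug: int = 359,
    n_disease: int = 1097,
    n_shared: int = 74,
    seed: int = 0,
) -> tuple[set[str], set[str], set[str]]:
    """Synthetic drug-target and disease-target symbol sets whose
    intersection is exactly ``n_shared`` planted symbols (the published
    hub symbols first, synthetic fillers after).

    Returns (drug_targets, disease_targets, planted_shared).
    """
    if n_shared > min(n_drug, n_disease):
        raise ValueError("n_shared cannot exceed either list size")
    shared = list(HUB_TARGETS)[: min(len(HUB_TARGETS), n_shared)]
    shared += _symbols("SHRD", n_shared - len(shared))
    drug_only = _symbols("DRUG", n_drug - n_shared)
    disease_only = _symbols("DIS", n_disease - n_shared)
    rng = np.random.default_rng(seed)
    drug = list(shared) + drug_only
    disease = list(shared) + disease_only
    rng.shuffle(drug)
    rng.shuffle(disease)
    return set(drug), set(disease), set(shared)


def make_scored_lists(
    keywords: tuple[str, ...] = ("pericardial effusion", "cardiomyopathy",
                                 "cardiotoxicity", "acute cardiac failure",
                                 "cardiac dysfunction"),
    n_per_list: int = 60,
    seed: int = 0,
) -> list[ScoredTargetList]:
    """Five GeneCards-style scored lists sharing a common core, with
    relevance scores spanning the >=10 screening floor."""
    rng = np.random.default_rng(seed)
    core = list(HUB_TARGETS)
    out = []
    for i, kw in enumerate(keywords):
        entries: dict[str, float] = {}
        for sym in core:
            entries[sym] = float(rng.uniform(15, 80))
        for j in range(n_per_list - len(core)):
            entries[f"G{i}{j:03d}"] = float(rng.uniform(2, 40))
        out.append(ScoredTargetList(source=kw, entries=entries))
    return out


def make_string_edges(
    path,
    n_background: int = 40,
    seed: int = 0,
) -> list[str]:
    """Write a STRING-dialect TSV with the ten published hubs densely wired
    at high confidence over a sparse low-confidence background.

    AKT1 is wired to every other hub (planted top hub); background nodes
    attach with scores straddling the 900 threshold.  Returns the planted
    hub symbols.
    """
    rng = np.random.default_rng(seed)
    hubs = list(HUB_TARGETS)
    rows = ["node1\tnode2\tcombined_score"]
    # dense high-confidence core: all hub pairs involving AKT1, plus a ring
    for i, u in enumerate(hubs):
        for v in hubs[i + 1:]:
            if u == "AKT1" or v == "AKT1" or abs(hubs.index(u) - hubs.index(v)) == 1:
                score = int(rng.integers(930, 1000))
                rows.append(f"{u}\t{v}\t{score}")
    background = _symbols("BG", n_background)
    for i, node in enumerate(background):
        partner = hubs[i % len(hubs)]
        score = int(rng.integers(400, 960))
        rows.append(f"{node}\t{partner}\t{score}")
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + "\n")
    return hubs


def make_gmt(path, universe: list[str], seed: int = 0, n_terms: int = 12) -> str:
    """Write a small GMT collection over ``universe`` with one planted
    term containing the published hub symbols.  Returns the planted term
    name."""
    rng = np.random.default_rng(seed)
    planted = "CARDIAC_SIGNALING_CORE"
    uni = sorted(universe)
    lines = [
        planted + "\tplanted hub-enriched set\t" +
        "\t".join(s for s in HUB_TARGETS if s in set(uni))
    ]
    for t in range(n_terms - 1):
        size = int(rng.integers(5, max(6, len(uni) // 3)))
        members = rng.choice(uni, size=min(size, len(uni)), replace=False)
        lines.append(f"RANDOM_SET_{t:02d}\trandom background set\t" + "\t".join(members))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return planted
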