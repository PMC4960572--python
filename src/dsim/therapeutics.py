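"""Therapeutic chemicals (TCs): loading, comparison and candidate ranking.

The working hypothesis is that similar diseases can be treated by common
therapeutic chemicals, so the curated TCs of a disease's significantly
similar neighbours are candidate treatments for the disease itself —
which matters most for diseases that carry no curated TC at all.

Associations arrive in a CTD-style chemicals-diseases TSV (``#``-prefixed
comment lines tolerated) with chemical id, chemical name, disease DOID
and an evidence column; only rows whose evidence marks a *therapeutic*
relationship enter the TC store (a "marker/mechanism" row is aetiology,
not treatment).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from dsim.errors import InputError

logger = logging.getLogger(__name__)

EXPECTED_COLUMNS = ("ChemicalID", "ChemicalName", "DiseaseID", "DirectEvidence")


@dataclass(frozen=True)
class Chemical:
    """A chemical keyed on its CTD (MeSH) id; the name is a display label."""

    id: str
    name: str = ""

    def __lt__(self, other: "Chemical") -> bool:
        return self.id < other.id


@dataclass
class CandidateTC:
    """A chemical proposed for ``query_disease`` via similar diseases.

    ``support`` lists, per supporting disease, the (DOID, method, score, q)
    of the best method call that made the disease significant.
    """

    chemical: Chemical
    query_disease: str
    support: list[tuple[str, str, float, float]] = field(default_factory=list)
    rank_score: float = 0.0

    @property
    def support_diseases(self) -> set[str]:
        return {d for d, _, _, _ in self.support}


def load_tcs(path) -> dict[str, set[Chemical]]:
    """Load therapeutic associations into a DOID -> chemical-set map.

    Diseases with no retained (therapeutic-evidence) row are absent keys,
    not empty sets — absence from the map mirrors absence from CTD.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except FileNotFoundError as exc:
        raise InputError(f"chemical-disease file not found: {path}") from exc
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"chemical-disease file is empty: {path}") from exc

    missing = [c for c in EXPECTED_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(
            "chemical-disease file lacks column(s) "
            f"{', '.join(missing)}; expected header {', '.join(EXPECTED_COLUMNS)}"
        )
    tc_map: dict[str, set[Chemical]] = {}
    n_kept = 0
    for row in df.dropna(subset=["ChemicalID", "DiseaseID"]).itertuples(index=False):
        evidence = (row.DirectEvidence or "")
        if "therapeutic" not in str(evidence).lower():
            continue
        chem = Chemical(id=str(row.ChemicalID).strip(),
                        name=str(row.ChemicalName or "").strip())
        tc_map.setdefault(str(row.DiseaseID).strip(), set()).add(chem)
        n_kept += 1
    logger.info("kept %d therapeutic rows over %d diseases from %s",
                n_kept, len(tc_map), path)
    return tc_map


def shared_tcs(d1: str, d2: str, tc_map: dict[str, set[Chemical]]) -> set[Chemical]:
    """TCs common to both diseases; empty when either is absent from the map."""
    return tc_map.get(d1, set()) & tc_map.get(d2, set())


def candidate_tcs(
    query: str,
    sig_records: pd.DataFrame,
    tc_map: dict[str, set[Chemical]],
    ranking: str = "score-sum",
    include_known: bool = False,
) -> list[CandidateTC]:
    """Rank candidate TCs for ``query`` from its significant neighbours.

    ``sig_records`` is a long (d1, d2, method, score, q) table already
    filtered to significant calls (q < alpha).  Each neighbour contributes
    its TCs; a chemical's rank score is, per strategy:

    * ``score-sum`` — the sum over supporting diseases of their best
      similarity score across methods;
    * ``support-count`` — the number of supporting diseases.

    Ties break on support count (or score sum, for ``support-count``),
    then ascending chemical id, for a deterministic total order.  TCs
    already curated for the query are excluded unless ``include_known``.
    """
    if ranking not in ("score-sum", "support-count"):
        raise InputError(f"unknown ranking strategy {ranking!r}")

    involves = sig_records[
        (sig_records["d1"] == query) | (sig_records["d2"] == query)
    ]
    # best significant method call per neighbour
    best: dict[str, tuple[str, float, float]] = {}
    for row in involves.itertuples(index=False):
        other = row.d2 if row.d1 == query else row.d1
        if other == query or pd.isna(row.score):
            continue
        cur = best.get(other)
        if cur is None or row.score > cur[1]:
            best[other] = (row.method, float(row.score), float(row.q))

    known = tc_map.get(query, set())
    candidates: dict[Chemical, CandidateTC] = {}
    for neighbour, (method, score, q) in best.items():
        for chem in tc_map.get(neighbour, set()):
            if chem in known and not include_known:
                continue
            cand = candidates.setdefault(
                chem, CandidateTC(chemical=chem, query_disease=query)
            )
            cand.support.append((neighbour, method, score, q))

    for cand in candidates.values():
        score_sum = sum(s for _, _, s, _ in cand.support)
        n_support = len(cand.support)
        cand.rank_score = score_sum if ranking == "score-sum" else float(n_support)

    def sort_key(c: CandidateTC):
        score_sum = sum(s for _, _, s, _ in c.support)
        n_support = len(c.support)
        if ranking == "score-sum":
            return (-c.rank_score, -n_support, c.chemical.id)
        return (-c.rank_score, -score_sum, c.chemical.id)

    ordered = sorted(candidates.values(), key=sort_key)
    for cand in ordered:
        cand.support.sort(key=lambda s: (-s[2], s[0]))
    return ordered


def export_network(
    d1: str, d2: str, tc_map: dict[str, set[Chemical]]
) -> dict:
    """Bipartite TC-disease network document for a disease pair.

    Nodes carry ``type`` "disease" or "chemical"; one edge per TC-disease
    association among the pair.  Shared chemicals thus have degree 2; a
    pair with no curated TC yields two disease nodes and no edge.
    """
    nodes = [
        {"id": d1, "type": "disease"},
        {"id": d2, "type": "disease"},
    ] if d1 != d2 else [{"id": d1, "type": "disease"}]
    edges = []
    chemicals: dict[str, str] = {}
    for disease in dict.fromkeys((d1, d2)):
        for chem in sorted(tc_map.get(disease, set())):
            chemicals.setdefault(chem.id, chem.name)
            edges.append({"source": chem.id, "target": disease,
                          "interaction": "therapeutic"})
    nodes += [
        {"id": cid, "type": "chemical", "name": name}
        for cid, name in sorted(chemicals.items())
    ]
    return {"nodes": nodes, "edges": edges}


def write_sif(network: dict, path) -> None:
    """Serialize a network document as SIF (``source<TAB>rel<TAB>target``)."""
    with open(path, "w") as fh:
        linked = set()
        for e in network["edges"]:
            fh.write(f"{e['source']}\t{e['interaction']}\t{e['target']}\n")
            linked |= {e["source"], e["target"]}
        for n in network["nodes"]:  # isolated nodes still listed
            if n["id"] not in linked:
                fh.write(f"{n['id']}\n")


def write_network_json(network: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(network, fh, indent=2, sort_keys=True)
        fh.write("\n")
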