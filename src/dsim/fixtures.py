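"""Synthetic input bundles with planted, known ground truth.

The generator emits a complete, file-backed input set — ontology (OBO),
disease-gene TSV, gene GO-BP GAF, weighted gene network TSV and a
CTD-style chemicals TSV — small enough to enumerate by hand yet rich
enough to exercise every measure end-to-end through the real readers.

The planted structure:

* the ontology is a complete ``branching``-ary ``is_a`` tree of the given
  depth; the leaves are the annotated diseases;
* each top-level branch owns a disjoint block of genes, GO-BP terms and
  network edges, so cross-branch disease pairs share nothing: they are
  the planted *dissimilar* pairs and score 0 under the IC-based and
  functional measures;
* within each branch, one sibling leaf pair is planted *similar*: the
  two share ``overlap_fraction`` of their genes (hence of their BP
  profiles) and of their therapeutic chemicals;
* for each planted similar pair, one chemical of the second disease is
  withheld from the first — recovering it by similarity transfer is the
  generator's built-in repositioning ground truth;
* one leaf outside every planted pair is omitted from the chemicals file
  altogether, emulating a disease absent from CTD.

Outputs are byte-identical for a fixed seed: all randomness flows from
one ``random.Random(seed)`` and every file is written in sorted order.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass
from pathlib import Path

from dsim.errors import InputError


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and noise parameters of one synthetic bundle."""

    depth: int = 3
    branching: int = 3
    n_genes: int = 180
    genes_per_disease: int = 8
    bp_per_gene: int = 3
    bp_per_branch: int = 60
    n_chemicals: int = 5
    overlap_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1 or self.branching < 1:
            raise InputError("depth and branching must be >= 1")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise InputError("overlap_fraction must lie in [0, 1]")
        if self.genes_per_disease < 1 or self.n_chemicals < 1:
            raise InputError("genes_per_disease and n_chemicals must be >= 1")
        per_block = self.n_genes // self.branching
        if per_block < 2 * self.genes_per_disease:
            raise InputError(
                "n_genes too small: each branch block needs at least "
                "2 * genes_per_disease genes"
            )

    @property
    def n_terms(self) -> int:
        return sum(self.branching ** k for k in range(self.depth + 1))


def _doid(i: int) -> str:
    return f"DOID:{i:07d}"


def make_fixture(spec: FixtureSpec, out_dir) -> dict:
    """Write the bundle into ``out_dir`` and return its manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)

    # ---- ontology: complete tree, BFS ids, root DOID:0000001 ------------
    parent_of: dict[str, str] = {}
    top_branch: dict[str, int] = {}
    level = [_doid(1)]
    next_id = 2
    for depth in range(1, spec.depth + 1):
        nxt = []
        for node in level:
            for b in range(spec.branching):
                child = _doid(next_id)
                next_id += 1
                parent_of[child] = node
                top_branch[child] = (
                    b if node == _doid(1) else top_branch[node]
                )
                nxt.append(child)
        level = nxt
    leaves = level
    all_terms = [_doid(i) for i in range(1, next_id)]

    obo_path = out / "ontology.obo"
    with open(obo_path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-disease\n")
        for term in all_terms:
            fh.write(f"\n[Term]\nid: {term}\nname: disease {term[-4:]}\n")
            if term in parent_of:
                fh.write(f"is_a: {parent_of[term]} ! parent\n")

    # ---- per-branch resource blocks -------------------------------------
    per_block = spec.n_genes // spec.branching
    gene_blocks = [
        [f"G{b * per_block + i:04d}" for i in range(per_block)]
        for b in range(spec.branching)
    ]
    bp_blocks = [
        [f"GO:{7000000 + b * spec.bp_per_branch + i:07d}"
         for i in range(spec.bp_per_branch)]
        for b in range(spec.branching)
    ]

    # ---- planted pairs ---------------------------------------------------
    # similar: the first two leaves of each branch share a sibling parent
    per_branch_leaves = len(leaves) // spec.branching
    branch_leaves = [
        leaves[b * per_branch_leaves:(b + 1) * per_branch_leaves]
        for b in range(spec.branching)
    ]
    similar_pairs = [
        (bl[0], bl[1]) for bl in branch_leaves if len(bl) >= 2
    ]
    dissimilar_pairs = [
        (branch_leaves[i][-1], branch_leaves[j][-1])
        for i in range(spec.branching)
        for j in range(i + 1, spec.branching)
    ]

    # ---- disease genes ---------------------------------------------------
    n_shared = round(spec.overlap_fraction * spec.genes_per_disease)
    genes_of: dict[str, list[str]] = {}
    for leaf in leaves:
        block = gene_blocks[top_branch[leaf]]
        genes_of[leaf] = sorted(rng.sample(block, spec.genes_per_disease))
    for a, b in similar_pairs:
        shared = sorted(rng.sample(genes_of[a], n_shared))
        rest_pool = sorted(set(gene_blocks[top_branch[b]]) - set(genes_of[a]))
        own = sorted(rng.sample(rest_pool, spec.genes_per_disease - n_shared))
        genes_of[b] = sorted(shared + own)

    with open(out / "disease_genes.tsv", "w") as fh:
        for leaf in leaves:
            for g in genes_of[leaf]:
                fh.write(f"{leaf}\t{g}\n")

    # ---- gene -> GO-BP (GAF 2.1) ----------------------------------------
    used_genes = sorted({g for gl in genes_of.values() for g in gl})
    branch_of_gene = {
        g: next(b for b in range(spec.branching) if g in set(gene_blocks[b]))
        for g in used_genes
    }
    bp_of: dict[str, list[str]] = {
        g: sorted(rng.sample(bp_blocks[branch_of_gene[g]], spec.bp_per_gene))
        for g in used_genes
    }
    with open(out / "gene_bp.gaf", "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for g in used_genes:
            for go in bp_of[g]:
                fh.write(
                    "FX\t{g}\t{g}\t\t{go}\tFX:0000001\tIEA\t\tP\t\t\t"
                    "gene\ttaxon:9606\t20160601\tFX\t\t\n".format(g=g, go=go)
                )

    # ---- gene network: a sparse ring module per disease gene set -------
    # a ring (not a clique) keeps chance connectivity between different
    # diseases' gene sets low, so best-match scores reflect planted gene
    # sharing rather than block-level edge density
    edges: dict[tuple[str, str], float] = {}
    for leaf in leaves:
        gl = genes_of[leaf]
        ring = list(zip(gl, gl[1:])) + ([(gl[-1], gl[0])] if len(gl) > 2 else [])
        for a, b in ring:
            key = tuple(sorted((a, b)))
            w = round(rng.uniform(1.0, 3.0), 3)
            edges[key] = max(edges.get(key, 0.0), w)
    with open(out / "gene_network.tsv", "w") as fh:
        for (a, b), w in sorted(edges.items()):
            fh.write(f"{a}\t{b}\t{w}\n")

    # ---- therapeutic chemicals ------------------------------------------
    n_shared_tc = round(spec.overlap_fraction * spec.n_chemicals)
    n_shared_tc = min(n_shared_tc, spec.n_chemicals - 1)  # keep 1 withheld
    leaf_index = {leaf: i for i, leaf in enumerate(leaves)}

    def chem(leaf: str, j: int) -> tuple[str, str]:
        li = leaf_index[leaf]
        return (f"MESH:C{li:03d}{j:02d}", f"chem-{li:03d}-{j:02d}")

    chems_of: dict[str, list[tuple[str, str]]] = {
        leaf: [chem(leaf, j) for j in range(spec.n_chemicals)]
        for leaf in leaves
    }
    withheld = []
    for a, b in similar_pairs:
        shared = chems_of[a][:n_shared_tc]
        own = [chem(b, j) for j in range(spec.n_chemicals - n_shared_tc)]
        chems_of[b] = shared + own
        withheld.append(
            {"query": a, "donor": b,
             "chemical_id": own[0][0], "chemical_name": own[0][1]}
        )

    in_planted = {d for pair in similar_pairs + dissimilar_pairs for d in pair}
    ctd_absent = next(l for l in leaves if l not in in_planted)

    with open(out / "chemicals.tsv", "w") as fh:
        fh.write("# synthetic CTD-style chemicals-diseases table\n")
        fh.write("ChemicalID\tChemicalName\tDiseaseID\tDirectEvidence\n")
        for leaf in leaves:
            if leaf == ctd_absent:
                continue
            for cid, cname in sorted(chems_of[leaf]):
                fh.write(f"{cid}\t{cname}\t{leaf}\ttherapeutic\n")

    manifest = {
        "spec": asdict(spec),
        "files": {
            "obo": "ontology.obo",
            "disease_genes": "disease_genes.tsv",
            "gaf": "gene_bp.gaf",
            "gene_net": "gene_network.tsv",
            "chemicals": "chemicals.tsv",
        },
        "root": _doid(1),
        "n_terms": spec.n_terms,
        "diseases": leaves,
        "similar_pairs": [list(p) for p in similar_pairs],
        "dissimilar_pairs": [list(p) for p in dissimilar_pairs],
        "withheld": withheld,
        "ctd_absent": ctd_absent,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
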