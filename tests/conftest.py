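"""Shared fixtures: tiny handcrafted ontologies and the default synthetic bundle."""

import pytest

from dsim import DataBundle, FixtureSpec, load_obo, make_fixture, run

CHAIN_OBO = """\
format-version: 1.2

[Term]
id: DOID:0000001
name: root

[Term]
id: DOID:0000002
name: a
is_a: DOID:0000001 ! root

[Term]
id: DOID:0000003
name: b
is_a: DOID:0000002 ! a
"""

DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: DOID:0000001
name: root

[Term]
id: DOID:0000002
name: x
is_a: DOID:0000001 ! root

[Term]
id: DOID:0000003
name: y
is_a: DOID:0000001 ! root

[Term]
id: DOID:0000004
name: z
is_a: DOID:0000002 ! x
is_a: DOID:0000003 ! y
"""

ROOT, A, B = "DOID:0000001", "DOID:0000002", "DOID:0000003"
X, Y, Z = "DOID:0000002", "DOID:0000003", "DOID:0000004"


def write_obo(tmp_path, text, name="test.obo"):
    path = tmp_path / name
    path.write_text(text)
    return path


@pytest.fixture
def chain_dag(tmp_path):
    """root <- a <- b."""
    return load_obo(write_obo(tmp_path, CHAIN_OBO))


@pytest.fixture
def diamond_dag(tmp_path):
    """root <- {x, y} <- z."""
    return load_obo(write_obo(tmp_path, DIAMOND_OBO))


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """Default synthetic input bundle written once per session."""
    out = tmp_path_factory.mktemp("bundle")
    manifest = make_fixture(FixtureSpec(), out)
    return out, manifest


@pytest.fixture(scope="session")
def bundle(bundle_dir):
    out, manifest = bundle_dir
    b = DataBundle.load(
        out / "ontology.obo",
        out / "disease_genes.tsv",
        gene_net=out / "gene_network.tsv",
        gaf=out / "gene_bp.gaf",
        chemicals=out / "chemicals.tsv",
    )
    return b, manifest


@pytest.fixture(scope="session")
def run_result(bundle):
    b, manifest = bundle
    return run(b), manifest


# ---------------------------------------------------------------------------
# Independent oracles (deliberately avoid the implementation's code paths)
# ---------------------------------------------------------------------------

def walk_ancestors(dag, term):
    """Self-inclusive ancestor closure by naive parent-following."""
    seen = {term}
    frontier = [term]
    while frontier:
        t = frontier.pop()
        for p in dag.terms[t].parents:
            if p not in seen:
                seen.add(p)
                frontier.append(p)
    return seen


def brute_resnik(t1, t2, dag, ic):
    """Exhaustive max-IC over hand-enumerated common ancestors."""
    common = walk_ancestors(dag, t1) & walk_ancestors(dag, t2)
    return max(ic.ic[a] for a in common if a in ic.ic)


def brute_lin(t1, t2, dag, ic):
    denom = ic.ic[t1] + ic.ic[t2]
    if denom == 0:
        return 0.0
    return 2.0 * brute_resnik(t1, t2, dag, ic) / denom


def path_svalues(t, dag, w=0.8):
    """Wang S-values by explicit path enumeration: max over paths of w^len."""
    out = {t: 1.0}

    def explore(node, contrib):
        for p in dag.terms[node].parents:
            c = contrib * w
            if c > out.get(p, 0.0):
                out[p] = c
            explore(p, c)

    explore(t, 1.0)
    return out


def brute_wang(t1, t2, dag, w=0.8):
    s1, s2 = path_svalues(t1, dag, w), path_svalues(t2, dag, w)
    shared = set(s1) & set(s2)
    return sum(s1[a] + s2[a] for a in shared) / (sum(s1.values()) + sum(s2.values()))
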