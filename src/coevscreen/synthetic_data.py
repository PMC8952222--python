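"""Synthetic orthologue-family generator with known coevolution ground truth.

The generator emulates the input a coevolution screen sees: a species tree
(random birth topology, exponential branch lengths), per-protein orthologue
alignments evolved along it under a BLOSUM62-derived reversible substitution
model with gamma site-rate heterogeneity, and — for positive-control
scenarios — designated inter-protein site pairs whose substitution events
co-occur on the same branches with a configurable coupling probability.

Two scenarios mirror the negative/positive control panels used to validate
coevolution screens: ``independent`` (no coupled sites, the analogue of a
database of non-interacting protein pairs) and ``coevolving`` (injected
coupled site pairs with recorded truth, the analogue of known complexes).

All outputs are deterministic functions of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from coevscreen.core_io import AMINO_ACIDS, Msa, PhyloTree, write_msa, write_newick
from coevscreen.rng import derive_rng
from coevscreen.substitution import background_frequencies, rate_matrix, score_table

__all__ = [
    "SimulationTruth",
    "simulate_species_tree",
    "evolve_protein",
    "inject_coevolution",
    "make_dataset",
    "derive_rng",
]

#: Default mean branch length, substitutions/site, of the simulated species
#: tree. 0.05 over ~60 edges of a 30-taxon tree gives a few substitutions per
#: unit-rate site — mammal-like divergence within a protein family.
DEFAULT_BRANCH_MEAN = 0.05

#: Relative substitution rate of injected coupled sites. Coupled sites are
#: modelled as moderately fast-evolving (twice the family average): sites
#: under correlated selection must vary to leave a detectable signal at all.
DEFAULT_COUPLED_RATE = 2.0


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    scenario: str
    species_tree: PhyloTree
    proteins: list[tuple[str, int, np.ndarray]] = field(default_factory=list)
    #: (protein_A, site_A, protein_B, site_B, coupling); sites 0-based here,
    #: written 1-based to the truth file.
    coupled_pairs: list[tuple[str, int, str, int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("independent", "coevolving"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "independent" and self.coupled_pairs:
            raise ValueError("independent scenario cannot carry coupled pairs")

    def validate(self) -> None:
        if (self.scenario == "independent") != (len(self.coupled_pairs) == 0):
            raise ValueError("coupled_pairs must be empty iff scenario=independent")
        lengths = {pid: n for pid, n, _ in self.proteins}
        for pa, a, pb, b, _ in self.coupled_pairs:
            if not (0 <= a < lengths[pa] and 0 <= b < lengths[pb]):
                raise ValueError(f"coupled site ({pa}:{a}, {pb}:{b}) out of range")


def simulate_species_tree(
    n_taxa: int,
    seed: int,
    branch_mean: float = DEFAULT_BRANCH_MEAN,
) -> PhyloTree:
    """A rooted random-birth species tree with exponential branch lengths."""
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = derive_rng(seed, "species-tree")
    children: dict[int, list[int]] = {0: []}
    leaves = [0]
    next_id = 1
    while len(leaves) < n_taxa:
        k = int(rng.integers(len(leaves)))
        node = leaves.pop(k)
        kids = [next_id, next_id + 1]
        next_id += 2
        children[node] = kids
        for c in kids:
            children[c] = []
        leaves.extend(kids)
    labels = [f"sp{i:03d}" for i in range(n_taxa)]
    order = rng.permutation(n_taxa)
    leaf_label = {leaf: labels[order[i]] for i, leaf in enumerate(sorted(leaves))}
    lengths = {}
    for node in sorted(children):
        if node != 0:
            lengths[node] = float(rng.exponential(branch_mean))
            if lengths[node] <= 0.0:  # exponential draws are a.s. positive
                lengths[node] = branch_mean * 1e-6

    def newick(node: int) -> str:
        if not children[node]:
            return f"{leaf_label[node]}:{lengths[node]!r}"
        inner = ",".join(newick(c) for c in children[node])
        if node == 0:
            return f"({inner});"
        return f"({inner}):{lengths[node]!r}"

    tree = PhyloTree.from_newick(newick(0))
    tree._tree.is_rooted = True
    return tree


def _tree_edges(tree: PhyloTree):
    """Preorder (node, parent, branch_length, leaf_label_or_None) tuples."""
    ids = {}
    out = []
    for node in tree._tree.preorder_node_iter():
        ids[id(node)] = len(ids)
        parent = node.parent_node
        out.append(
            (
                ids[id(node)],
                ids[id(parent)] if parent is not None else None,
                float(node.edge.length or 0.0),
                node.taxon.label if node.is_leaf() else None,
            )
        )
    return out


def _jump_probs(q: np.ndarray) -> np.ndarray:
    j = q.copy()
    np.fill_diagonal(j, 0.0)
    return j / j.sum(axis=1, keepdims=True)


def _evolve_branch(
    states: np.ndarray,
    rates: np.ndarray,
    t: float,
    rng: np.random.Generator,
    q: np.ndarray,
    jump: np.ndarray,
) -> np.ndarray:
    """Evolve every site independently along one branch (Gillespie)."""
    out = states.copy()
    if t <= 0.0:
        return out
    for s in range(out.size):
        r = rates[s]
        if r <= 0.0:
            continue
        x = int(out[s])
        rem = t
        while True:
            lam = -q[x, x] * r
            dt = rng.exponential(1.0 / lam)
            if dt >= rem:
                break
            rem -= dt
            x = int(rng.choice(20, p=jump[x]))
        out[s] = x
    return out


def evolve_protein(
    tree: PhyloTree,
    length: int,
    rate_shape: float,
    seed: int,
    rates: np.ndarray | None = None,
) -> tuple[Msa, np.ndarray]:
    """Evolve a gap-free protein alignment along the species tree.

    The root sequence is drawn from the BLOSUM62-implied equilibrium
    frequencies; per-site rates are gamma(shape=``rate_shape``, mean 1)
    unless supplied explicitly.  Returns the leaf alignment (rows sorted by
    species label) and the site-rate vector.
    """
    rng = derive_rng(seed, "evolve")
    if rates is None:
        if rate_shape <= 0:
            raise ValueError("rate_shape must be positive")
        rates = rng.gamma(rate_shape, 1.0 / rate_shape, size=length)
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (length,):
        raise ValueError("rates length mismatch")
    q = rate_matrix()
    jump = _jump_probs(q)
    pi = background_frequencies()
    root_states = rng.choice(20, size=length, p=pi)
    node_states: dict[int, np.ndarray] = {}
    leaf_rows: dict[str, np.ndarray] = {}
    for node, parent, blen, label in _tree_edges(tree):
        if parent is None:
            node_states[node] = root_states
        else:
            node_states[node] = _evolve_branch(
                node_states[parent], rates, blen, rng, q, jump
            )
        if label is not None:
            leaf_rows[label] = node_states[node]
    rows = [
        (sp, "".join(AMINO_ACIDS[c] for c in leaf_rows[sp]))
        for sp in sorted(leaf_rows)
    ]
    return Msa("protein", rows), rates


def _coupled_target(
    b_state: int, a_state: int, rng: np.random.Generator, score: np.ndarray,
    pi: np.ndarray,
) -> int:
    """Residue for a forced substitution at B: compatible (BLOSUM score >= 0)
    with the new residue at A, never the current residue."""
    ok = np.where((score[:20, a_state] >= 0))[0]
    ok = ok[ok != b_state]
    if ok.size == 0:
        ok = np.array([x for x in range(20) if x != b_state])
    w = pi[ok]
    return int(rng.choice(ok, p=w / w.sum()))


def _joint_branch(
    a: int,
    b: int,
    t: float,
    coupling: float,
    rate: float,
    rng: np.random.Generator,
    q: np.ndarray,
    jump: np.ndarray,
    score: np.ndarray,
    pi: np.ndarray,
) -> tuple[int, int, int, int]:
    """Evolve one coupled site pair along a branch.

    Each substitution event at site A forces, with probability ``coupling``,
    a simultaneous substitution at site B (to a residue scoring >= 0 against
    A's new state); B's own independent events are correspondingly thinned by
    ``1 - coupling``.  Returns (a_end, b_end, n_events_a, n_events_b).
    """
    # trajectory of A: (time, new_state)
    a_events: list[tuple[float, int]] = []
    x = a
    tau = 0.0
    while t > 0.0:
        lam = -q[x, x] * rate
        tau += rng.exponential(1.0 / lam)
        if tau >= t:
            break
        x = int(rng.choice(20, p=jump[x]))
        a_events.append((tau, x))
    a_end = x

    forced = [(tt, xx) for (tt, xx) in a_events if rng.random() < coupling]
    y = b
    tau = 0.0
    n_b = 0
    fi = 0
    while t > 0.0:
        lam = -q[y, y] * rate
        dt = rng.exponential(1.0 / lam)
        nxt_forced = forced[fi][0] if fi < len(forced) else np.inf
        if tau + dt < nxt_forced:
            tau += dt
            if tau >= t:
                break
            if rng.random() < 1.0 - coupling:  # thinned independent event
                y = int(rng.choice(20, p=jump[y]))
                n_b += 1
        else:
            if nxt_forced >= t:
                break
            tau = nxt_forced
            y = _coupled_target(y, forced[fi][1], rng, score, pi)
            n_b += 1
            fi += 1
    return a_end, y, len(a_events), n_b


def inject_coevolution(
    msa_a: Msa,
    msa_b: Msa,
    tree: PhyloTree,
    pairs: list[tuple[int, int]],
    coupling: float,
    seed: int,
    site_rate: float = DEFAULT_COUPLED_RATE,
) -> tuple[Msa, Msa, list[dict]]:
    """Overwrite designated column pairs with jointly evolved columns.

    ``pairs`` are 0-based (site_in_A, site_in_B) tuples; no site may appear
    twice.  Returns the modified alignments and a per-pair event record
    (branch-level substitution counts), used to verify forced co-occurrence.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must be in [0, 1]")
    if len({a for a, _ in pairs}) != len(pairs) or len(
        {b for _, b in pairs}
    ) != len(pairs):
        raise ValueError("overlapping coupled sites")
    for a, b in pairs:
        if not (0 <= a < msa_a.length and 0 <= b < msa_b.length):
            raise ValueError(f"coupled site ({a},{b}) outside protein length")
    q = rate_matrix()
    jump = _jump_probs(q)
    score = score_table("BLOSUM62")
    pi = background_frequencies()
    edges = _tree_edges(tree)
    cols_a = {sp: list(seq) for sp, seq in msa_a.rows}
    cols_b = {sp: list(seq) for sp, seq in msa_b.rows}
    records = []
    for k, (site_a, site_b) in enumerate(pairs):
        rng = derive_rng(seed, "couple", k)
        root_a = int(rng.choice(20, p=pi))
        root_b = int(rng.choice(20, p=pi))
        states: dict[int, tuple[int, int]] = {}
        events = []
        for node, parent, blen, label in edges:
            if parent is None:
                states[node] = (root_a, root_b)
            else:
                a0, b0 = states[parent]
                a1, b1, na, nb = _joint_branch(
                    a0, b0, blen, coupling, site_rate, rng, q, jump, score, pi
                )
                states[node] = (a1, b1)
                events.append({"node": node, "events_a": na, "events_b": nb})
            if label is not None:
                a1, b1 = states[node]
                cols_a[label][site_a] = AMINO_ACIDS[a1]
                cols_b[label][site_b] = AMINO_ACIDS[b1]
        records.append(
            {"site_a": site_a, "site_b": site_b, "branch_events": events}
        )
    new_a = Msa(msa_a.protein_id, [(sp, "".join(cols_a[sp])) for sp, _ in msa_a.rows])
    new_b = Msa(msa_b.protein_id, [(sp, "".join(cols_b[sp])) for sp, _ in msa_b.rows])
    return new_a, new_b, records


def _inject_gaps(msa: Msa, fraction: float, rng: np.random.Generator) -> Msa:
    """Gap out random row blocks until roughly ``fraction`` of cells are gaps."""
    rows = [list(seq) for _, seq in msa.rows]
    total = msa.n_rows * msa.length
    target = int(fraction * total)
    placed = 0
    while placed < target:
        r = int(rng.integers(msa.n_rows))
        start = int(rng.integers(msa.length))
        width = 1 + int(rng.geometric(0.1))
        for c in range(start, min(start + width, msa.length)):
            if rows[r][c] != "-":
                rows[r][c] = "-"
                placed += 1
    return Msa(
        msa.protein_id,
        [(sp, "".join(chars)) for (sp, _), chars in zip(msa.rows, rows)],
    )


def make_dataset(
    scenario: str,
    n_proteins: int,
    n_taxa: int,
    length: int,
    coupling: float,
    seed: int,
    out_dir: str | Path,
    n_coupled: int = 10,
    rate_shape: float = 1.0,
    branch_mean: float = DEFAULT_BRANCH_MEAN,
    coupled_rate: float = DEFAULT_COUPLED_RATE,
    gap_fraction: float = 0.0,
) -> SimulationTruth:
    """Write a complete, pipeline-ready input set with ground truth.

    Produces ``msa/<protein>.fasta`` (aligned, one sequence per species),
    ``tree.nwk``, ``proteins.txt``, ``species.txt`` and ``truth.tsv`` (sites
    1-based) under ``out_dir``.  In the ``coevolving`` scenario the coupled
    site pairs connect the first two proteins.
    """
    out = Path(out_dir)
    (out / "msa").mkdir(parents=True, exist_ok=True)
    tree = simulate_species_tree(n_taxa, seed, branch_mean)
    protein_ids = [f"prot{i + 1:02d}" for i in range(n_proteins)]
    msas: dict[str, Msa] = {}
    truth = SimulationTruth(
        scenario=scenario, species_tree=tree, seed=seed, coupled_pairs=[]
    )
    for i, pid in enumerate(protein_ids):
        msa, rates = evolve_protein(
            tree, length, rate_shape, seed=int(derive_rng(seed, pid).integers(2**31))
        )
        msa.protein_id = pid
        msas[pid] = msa
        truth.proteins.append((pid, length, rates))

    if scenario == "coevolving":
        if n_proteins < 2:
            raise ValueError("coevolving scenario needs at least 2 proteins")
        pa, pb = protein_ids[0], protein_ids[1]
        rng = derive_rng(seed, "site-choice")
        sites_a = rng.choice(length, size=n_coupled, replace=False)
        sites_b = rng.choice(length, size=n_coupled, replace=False)
        pairs = [(int(a), int(b)) for a, b in zip(sites_a, sites_b)]
        msas[pa], msas[pb], _ = inject_coevolution(
            msas[pa], msas[pb], tree, pairs, coupling, seed, coupled_rate
        )
        truth.coupled_pairs = [(pa, a, pb, b, coupling) for a, b in pairs]

    if gap_fraction > 0.0:
        for pid in protein_ids:
            msas[pid] = _inject_gaps(
                msas[pid], gap_fraction, derive_rng(seed, "gaps", pid)
            )

    for pid in protein_ids:
        write_msa(msas[pid], out / "msa" / f"{pid}.fasta")
    write_newick(tree, out / "tree.nwk")
    (out / "proteins.txt").write_text(
        "\n".join(protein_ids) + "\n", encoding="utf-8"
    )
    (out / "species.txt").write_text(
        "\n".join(sorted(tree.leaf_labels)) + "\n", encoding="utf-8"
    )
    lines = ["protein_A\tsite_A\tprotein_B\tsite_B\tcoupling"]
    for pa, a, pb, b, c in truth.coupled_pairs:
        lines.append(f"{pa}\t{a + 1}\t{pb}\t{b + 1}\t{c}")
    (out / "truth.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    truth.validate()
    return truth
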