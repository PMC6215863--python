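"""Synthetic genomes, operons and gene families with known ground truth.

Everything the pipeline consumes can be generated here with a recorded
truth object, so detection power is measurable without downloads:

* host genomes sampled from a Markov compositional model, with coding genes
  drawn from a codon-usage table (so both the k-mer and the codon methods
  see a realistic signal);
* operon-sized inserts (three same-strand genes, CAB order, spanning
  ~2730 nt on average — the typical xmoCAB operon size) drawn from a
  compositionally distinct donor model and implanted at known coordinates;
* three-gene amino-acid alignments evolved on a known tree, optionally
  with one gene's focal clade regrafted elsewhere (topology swap, the
  "xmoB pattern") and/or a clade branch-rate multiplier (the accelerated
  third-operon pattern).

All randomness flows from one integer seed through
``numpy.random.SeedSequence.spawn``, one child stream per generation stage,
so identical seeds give byte-identical outputs and stages are individually
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np

from .composition import CODONS, STOP_CODONS
from .genome_io import CdsFeature, GenomeRecord, OperonLocus, reverse_complement
from .phylo import Alignment, GeneTree, Node

_BASES = "ACGT"

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Default study conditions: clearly separated host/donor signatures and a
# 12-taxon ultrametric base tree (ingroup depth 0.4 substitutions/site,
# internal branches 0.1) with a 3-leaf focal clade attached at the ingroup
# root — so a clade rate multiplier maps directly onto the root-to-tip
# ratio — and a 2-leaf outgroup.
DEFAULT_HOST_GC = 0.40
DEFAULT_DONOR_GC = 0.60
DEFAULT_BASE_TREE_NEWICK = (
    "((((V1:0.1,V2:0.1):0.1,V3:0.2):0.2,"
    "(((B1:0.1,B2:0.1):0.1,(B3:0.1,B4:0.1):0.1):0.1,"
    "((B5:0.1,B6:0.1):0.1,B7:0.2):0.1):0.1):0.15,"
    "(O1:0.2,O2:0.2):0.2);"
)
FOCAL_CLADE = frozenset({"V1", "V2", "V3"})
OUTGROUP = frozenset({"O1", "O2"})
SWAP_ATTACH = frozenset({"B5", "B6", "B7"})
# Acceleration of the third-operon lineage in the third gene family, the
# default contrast exercised by the rate-recovery study.
DEFAULT_RATE_MULTIPLIER = 3.46
DEFAULT_SWAP_GENE = 2
DEFAULT_RATE_GENE = 3


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Markov compositional models
# ---------------------------------------------------------------------------


@dataclass
class MarkovModel:
    """Order-k Markov chain over {A,C,G,T}; rows of ``probs`` sum to 1."""

    order: int
    probs: np.ndarray  # shape (4**order, 4)
    label: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.order < 0:
            raise ValueError("order must be >= 0")
        if self.probs.shape != (4**self.order, 4):
            raise ValueError(
                f"probs must have shape ({4 ** self.order}, 4), got {self.probs.shape}"
            )
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each conditional distribution must sum to 1")
        if (self.probs < 0).any():
            raise ValueError("negative probabilities")

    @classmethod
    def from_gc(cls, gc: float, order: int = 0, label: str = "") -> "MarkovModel":
        """I.i.d. (order given, identical rows) model with target GC content."""
        row = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        return cls(order=order, probs=np.tile(row, (4**order, 1)),
                   label=label or f"gc{gc:.2f}")

    @property
    def stationary_gc(self) -> float:
        marg = self.probs.mean(axis=0)  # exact for identical rows
        return float(marg[1] + marg[2])


def _sample_chain(model: MarkovModel, length: int, rng: np.random.Generator) -> str:
    """Sample a sequence from the chain (short burn-in reaches stationarity)."""
    if length <= model.order:
        raise ValueError(f"length ({length}) must exceed model order ({model.order})")
    if model.order == 0:
        idx = rng.choice(4, size=length, p=model.probs[0])
        return "".join(_BASES[i] for i in idx)
    burn = 50 + model.order
    cum = np.cumsum(model.probs, axis=1)
    u = rng.random(length + burn)
    mask = 4**model.order - 1
    ctx = 0
    out = []
    for t in range(length + burn):
        b = int(np.searchsorted(cum[ctx], u[t], side="right"))
        b = min(b, 3)
        out.append(b)
        ctx = ((ctx << 2) | b) & mask
    return "".join(_BASES[i] for i in out[burn:])


def gen_genome(model: MarkovModel, length: int, seed) -> GenomeRecord:
    """A featureless genome sampled from the compositional model."""
    rng = _rng(seed)
    return GenomeRecord(
        id=f"synth_{model.label}", sequence=_sample_chain(model, length, rng)
    )


# ---------------------------------------------------------------------------
# Codon-usage models and coding sequence
# ---------------------------------------------------------------------------


def gc_biased_codon_usage(gc: float) -> np.ndarray:
    """A sense-codon usage table whose GC content targets ``gc``.

    Codon weights are gc^g * (1-gc)^(3-g) with g the codon's G+C count;
    stop codons get zero mass (stops are handled terminally).
    """
    w = np.array(
        [
            0.0
            if c in STOP_CODONS
            else (gc ** sum(b in "GC" for b in c))
            * ((1 - gc) ** sum(b in "AT" for b in c))
            for c in CODONS
        ]
    )
    return w / w.sum()


def gen_codon_cds(usage: np.ndarray, n_codons: int, seed) -> str:
    """I.i.d. codon draws from ``usage`` plus one terminal stop (TAA).

    ``usage`` is a length-64 distribution over :data:`~xenocomp.composition.CODONS`;
    any mass on stop codons is rejected (stops are terminal-only here).
    """
    usage = np.asarray(usage, dtype=float)
    if usage.shape != (64,):
        raise ValueError("usage must be a length-64 distribution")
    if not np.isclose(usage.sum(), 1.0):
        raise ValueError("usage must sum to 1")
    stops = [CODONS.index(s) for s in STOP_CODONS]
    if usage[stops].sum() > 0:
        raise ValueError("usage assigns mass to stop codons (stops are terminal-only)")
    rng = _rng(seed)
    idx = rng.choice(64, size=n_codons, p=usage)
    return "".join(CODONS[i] for i in idx) + "TAA"


# ---------------------------------------------------------------------------
# Operon inserts and implantation
# ---------------------------------------------------------------------------

_LABELS = {"CAB": ("xmoC", "xmoA", "xmoB"), "ABC": ("xmoA", "xmoB", "xmoC")}


def gen_operon_insert(
    donor: MarkovModel,
    length_mean: int = 2730,
    length_sd: int = 300,
    seed=None,
    order: Literal["CAB", "ABC"] = "CAB",
    codon_usage: np.ndarray | None = None,
) -> tuple[str, OperonLocus]:
    """A three-gene same-strand operon insert drawn from a donor model.

    The spanning length is a normal draw (default mean 2730 nt, the average
    xmoCAB operon size) truncated at 1500; the three CDS (lengths multiples
    of 3) come from the donor's codon-usage table and the two intergenic
    gaps from the donor chain.  Returns the insert sequence and an
    :class:`OperonLocus` with coordinates relative to the insert start
    (genome_id is filled in at implantation).
    """
    if length_mean <= 3 * 450:
        raise ValueError("length_mean too small for three genes")
    if length_sd <= 0:
        raise ValueError("length_sd must be positive")
    rng = _rng(seed)
    span = max(1500, int(round(rng.normal(length_mean, length_sd))))
    coding = span - 60
    gene_len = (coding // 9) * 3
    if gene_len < 150:
        raise ValueError("degenerate length parameters: genes too short")
    extra = coding - 3 * gene_len
    gap1 = 30 + extra // 2
    gap2 = 30 + extra - extra // 2
    usage = codon_usage if codon_usage is not None else gc_biased_codon_usage(
        donor.stationary_gc
    )
    labels = _LABELS[order]
    pieces: list[str] = []
    genes: list[tuple[str, CdsFeature]] = []
    pos = 0
    for gi, label in enumerate(labels):
        cds = gen_codon_cds(usage, gene_len // 3 - 1, rng)
        pieces.append(cds)
        genes.append(
            (label, CdsFeature(gene_id=label, start=pos, end=pos + gene_len, strand="+"))
        )
        pos += gene_len
        if gi < 2:
            gap = gap1 if gi == 0 else gap2
            pieces.append(_sample_chain(donor, gap, rng))
            pos += gap
    seq = "".join(pieces)
    assert len(seq) == span and pos == span
    locus = OperonLocus(genome_id="", operon_id="operon", genes=genes)
    return seq, locus


@dataclass
class SyntheticTruth:
    """Ground-truth record for parameter-recovery tests."""

    genome_id: str = ""
    inserts: list[dict] = field(default_factory=list)
    gene_trees: dict[int, str] = field(default_factory=dict)
    topology_swap: dict[int, bool] = field(default_factory=dict)
    rate_multiplier: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def implant(
    host: GenomeRecord,
    inserts: Sequence[tuple[str, OperonLocus, str]],
    seed,
    min_spacing: int = 5000,
) -> tuple[GenomeRecord, list[OperonLocus], SyntheticTruth]:
    """Implant insert sequences at random non-overlapping host positions.

    Insertion points are uniform over the host, pairwise at least
    ``min_spacing`` apart, and never inside an existing host feature.
    Downstream feature and locus coordinates are shifted; truth records the
    final (absolute) insert intervals and donor labels.
    """
    total = sum(len(s) for s, _, _ in inserts)
    if total >= len(host.sequence) / 10:
        raise ValueError("total insert length must be < host length / 10")
    rng = _rng(seed)
    n = len(inserts)
    hostlen = len(host.sequence)

    allowed = np.ones(hostlen + 1, dtype=bool)
    for f in host.features:
        allowed[f.start + 1 : f.end] = False  # strictly inside a feature
    candidates = np.nonzero(allowed)[0]

    positions: np.ndarray | None = None
    for _ in range(1000):
        cand = np.sort(rng.choice(candidates, size=n, replace=False))
        if n > 1 and np.min(np.diff(cand)) < min_spacing:
            continue
        positions = cand
        break
    if positions is None:
        raise ValueError("cannot satisfy insert spacing constraints")

    seq_parts: list[str] = []
    new_loci: list[OperonLocus] = []
    truth = SyntheticTruth(genome_id=host.id, seed=None)
    prev = 0
    shift = 0
    for (ins_seq, locus, donor_label), p in zip(inserts, positions):
        p = int(p)
        seq_parts.append(host.sequence[prev:p])
        start_abs = p + shift
        new_loci.append(
            OperonLocus(
                genome_id=host.id,
                operon_id=locus.operon_id,
                genes=[
                    (
                        label,
                        CdsFeature(
                            gene_id=f"{locus.operon_id}_{label}",
                            start=f.start + start_abs,
                            end=f.end + start_abs,
                            strand=f.strand,
                        ),
                    )
                    for label, f in locus.genes
                ],
            )
        )
        truth.inserts.append(
            {
                "start": start_abs,
                "end": start_abs + len(ins_seq),
                "donor": donor_label,
                "operon_id": locus.operon_id,
            }
        )
        seq_parts.append(ins_seq)
        shift += len(ins_seq)
        prev = p
    seq_parts.append(host.sequence[prev:])

    # shift host features past each insertion point
    new_features: list[CdsFeature] = []
    for f in host.features:
        offset = sum(
            len(s) for (s, _, _), p in zip(inserts, positions) if p <= f.start
        )
        new_features.append(
            CdsFeature(
                gene_id=f.gene_id,
                start=f.start + offset,
                end=f.end + offset,
                strand=f.strand,
                phase=f.phase,
            )
        )
    for locus in new_loci:
        new_features.extend(f for _, f in locus.genes)

    genome = GenomeRecord(
        id=host.id,
        sequence="".join(seq_parts),
        topology=host.topology,
        features=new_features,
    )
    genome.validate_features()
    return genome, new_loci, truth


def gen_coding_genome(
    model: MarkovModel,
    usage: np.ndarray,
    length: int,
    seed,
    genome_id: str = "synth_host",
) -> GenomeRecord:
    """A host genome of alternating coding genes and intergenic spacers.

    Genes (600–1200 nt, random strand) are drawn from the codon-usage
    table; spacers (100–200 nt) from the Markov model.  Gives the codon
    method a genome-wide usage signal to compare operons against.
    """
    rng = _rng(seed)
    parts: list[str] = []
    features: list[CdsFeature] = []
    pos = 0
    gi = 0
    while True:
        spacer = int(rng.integers(100, 201))
        gene_nt = 3 * int(rng.integers(200, 401))
        if pos + spacer + gene_nt > length - 100:
            break
        parts.append(_sample_chain(model, spacer, rng))
        pos += spacer
        cds = gen_codon_cds(usage, gene_nt // 3 - 1, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        parts.append(cds if strand == "+" else reverse_complement(cds))
        features.append(
            CdsFeature(
                gene_id=f"{genome_id}_g{gi:04d}",
                start=pos,
                end=pos + gene_nt,
                strand=strand,
            )
        )
        pos += gene_nt
        gi += 1
    parts.append(_sample_chain(model, length - pos, rng))
    genome = GenomeRecord(id=genome_id, sequence="".join(parts), features=features)
    assert len(genome.sequence) == length
    return genome


# ---------------------------------------------------------------------------
# The LGT study scenario
# ---------------------------------------------------------------------------


@dataclass
class LgtScenario:
    genome: GenomeRecord
    loci: list[OperonLocus]
    truth: SyntheticTruth
    host_model: MarkovModel
    donor_model: MarkovModel


def lgt_scenario(
    seed: int,
    host_length: int = 200_000,
    host_gc: float = DEFAULT_HOST_GC,
    donor_gc: float = DEFAULT_DONOR_GC,
    n_foreign: int = 2,
    n_native: int = 2,
) -> LgtScenario:
    """The default compositional-LGT study: a host genome with implanted
    foreign (donor-composition) and native (host-composition) operons.

    Foreign operons emulate recently transferred xmoCAB; native operons are
    the matched controls that should rank below them in the KL table.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    host_model = MarkovModel.from_gc(host_gc, label="host")
    donor_model = MarkovModel.from_gc(donor_gc, label="donor")
    host_usage = gc_biased_codon_usage(host_gc)

    gid = f"synth_host_s{seed}"
    host = gen_coding_genome(host_model, host_usage, host_length, ss[0], genome_id=gid)

    op_rng = _rng(ss[1])
    inserts: list[tuple[str, OperonLocus, str]] = []
    for i in range(n_foreign):
        seq, locus = gen_operon_insert(donor_model, seed=op_rng)
        locus.operon_id = f"foreign_{i + 1}"
        inserts.append((seq, locus, donor_model.label))
    for i in range(n_native):
        seq, locus = gen_operon_insert(host_model, seed=op_rng)
        locus.operon_id = f"native_{i + 1}"
        inserts.append((seq, locus, host_model.label))

    genome, loci, truth = implant(host, inserts, ss[2])
    truth.seed = seed
    return LgtScenario(
        genome=genome, loci=loci, truth=truth,
        host_model=host_model, donor_model=donor_model,
    )


# ---------------------------------------------------------------------------
# Gene-family simulation on trees
# ---------------------------------------------------------------------------


def _regraft(tree: GeneTree, clade: frozenset[str], attach_above: frozenset[str]) -> GeneTree:
    """Move the named clade onto the midpoint of the edge above another clade."""
    if clade & attach_above:
        raise ValueError("regraft target overlaps the moved clade")
    t = tree.copy()
    cnode = t.find_clade(clade)
    parent = _parent_of(t, cnode)
    if parent is None:
        raise ValueError("cannot regraft the whole tree")
    parent.children.remove(cnode)
    if len(parent.children) == 1:
        only = parent.children[0]
        grand = _parent_of(t, parent)
        only.length += parent.length
        if grand is None:
            only.length = 0.0
            t.root = only
        else:
            grand.children[grand.children.index(parent)] = only
    anode = t.find_clade(attach_above)
    aparent = _parent_of(t, anode)
    if aparent is None:
        raise ValueError("cannot attach above the root")
    half = anode.length / 2
    joint = Node(length=half, children=[anode, cnode])
    anode.length = half
    aparent.children[aparent.children.index(anode)] = joint
    return t


def _parent_of(tree: GeneTree, target: Node) -> Node | None:
    for node in tree.postorder():
        if target in node.children:
            return node
    return None


def _scale_clade(tree: GeneTree, clade: frozenset[str], multiplier: float) -> GeneTree:
    """Scale branch lengths within the clade, including its stem branch."""
    if multiplier <= 0:
        raise ValueError("rate multiplier must be positive")
    t = tree.copy()
    cnode = t.find_clade(clade)
    stack = [cnode]
    while stack:
        node = stack.pop()
        node.length *= multiplier
        stack.extend(node.children)
    return t


def _evolve_on_tree(tree: GeneTree, seq_len: int, rng: np.random.Generator) -> Alignment:
    """Poisson (equal-rates) amino-acid evolution along the tree.

    Per site, replacement events arrive as Poisson(branch length); each
    event replaces the residue with one of the other 19 uniformly, so
    branch length equals expected substitutions per site.
    """
    # P(back at the starting residue after k uniform-other-19 replacements)
    a = [1.0]
    for _ in range(64):
        a.append((1 - a[-1]) / 19.0)
    a = np.array(a)

    def mutate(parent: np.ndarray, b: float) -> np.ndarray:
        child = parent.copy()
        k = rng.poisson(b, size=seq_len)
        hit = np.nonzero(k > 0)[0]
        if hit.size == 0:
            return child
        stay = rng.random(hit.size) < a[np.minimum(k[hit], 64)]
        change = hit[~stay]
        r = rng.integers(0, 19, size=change.size)
        orig = parent[change]
        child[change] = r + (r >= orig)
        return child

    names: list[str] = []
    rows: list[str] = []

    def rec(node: Node, state: np.ndarray) -> None:
        if node.is_leaf:
            names.append(node.name)
            rows.append("".join(AA_ALPHABET[i] for i in state))
            return
        for c in node.children:
            rec(c, mutate(state, c.length))

    root_state = rng.integers(0, 20, size=seq_len)
    rec(tree.root, root_state)
    return Alignment(names=names, rows=rows)


def sim_gene_families(
    base_tree: GeneTree | str | None = None,
    n_genes: int = 3,
    swaps: dict[int, tuple[frozenset[str], frozenset[str]]] | None = None,
    rate_multipliers: dict[int, tuple[frozenset[str], float]] | None = None,
    seq_len: int = 500,
    seed=0,
) -> tuple[list[Alignment], SyntheticTruth]:
    """Evolve ``n_genes`` ungapped amino-acid alignments on a shared tree.

    ``swaps`` maps 1-based gene index -> (clade leaves, attach-above clade):
    that gene evolves on a tree with the clade regrafted (a single-gene
    transfer, the verrucomicrobial xmoB pattern).  ``rate_multipliers``
    maps gene index -> (clade leaves, multiplier): the clade's branches
    (including its stem) are scaled for that gene (the accelerated
    third-operon pattern).
    """
    if base_tree is None:
        base_tree = DEFAULT_BASE_TREE_NEWICK
    if isinstance(base_tree, str):
        base_tree = GeneTree.from_newick(base_tree)
    swaps = swaps or {}
    rate_multipliers = rate_multipliers or {}
    rng = _rng(seed)
    truth = SyntheticTruth(seed=seed if isinstance(seed, int) else None)
    alignments: list[Alignment] = []
    for g in range(1, n_genes + 1):
        tree_g = base_tree
        if g in swaps:
            clade, attach = swaps[g]
            tree_g = _regraft(tree_g, frozenset(clade), frozenset(attach))
            truth.topology_swap[g] = True
        else:
            truth.topology_swap[g] = False
        if g in rate_multipliers:
            clade, mult = rate_multipliers[g]
            tree_g = _scale_clade(tree_g, frozenset(clade), mult)
            truth.rate_multiplier[f"gene{g}:{'+'.join(sorted(clade))}"] = mult
        truth.gene_trees[g] = tree_g.to_newick()
        alignments.append(_evolve_on_tree(tree_g, seq_len, rng))
    return alignments, truth


def default_gene_family_scenario(
    seed: int, seq_len: int = 500, swap: bool = True, rates: bool = True
) -> tuple[list[Alignment], SyntheticTruth]:
    """The default 3-gene study on the 12-taxon tree: gene 2 carries the
    topology swap, gene 3 the focal-clade rate multiplier."""
    swaps = {DEFAULT_SWAP_GENE: (FOCAL_CLADE, SWAP_ATTACH)} if swap else None
    mults = (
        {DEFAULT_RATE_GENE: (FOCAL_CLADE, DEFAULT_RATE_MULTIPLIER)} if rates else None
    )
    return sim_gene_families(
        n_genes=3, swaps=swaps, rate_multipliers=mults, seq_len=seq_len, seed=seed
    )


# ---------------------------------------------------------------------------
# Random trees (used by consistency studies)
# ---------------------------------------------------------------------------


def random_tree(
    names: Sequence[str], seed, min_branch: float = 0.1, max_branch: float = 1.0
) -> GeneTree:
    """A random binary tree: repeated joins of uniformly chosen subtrees,
    branch lengths uniform in [min_branch, max_branch]."""
    rng = _rng(seed)
    if len(names) < 3:
        raise ValueError("need at least 3 taxa")
    subtrees = [Node(name=n) for n in names]
    while len(subtrees) > 2:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(int(j))
        a = subtrees.pop(int(i))
        a.length = float(rng.uniform(min_branch, max_branch))
        b.length = float(rng.uniform(min_branch, max_branch))
        subtrees.append(Node(children=[a, b]))
    a, b = subtrees
    a.length = float(rng.uniform(min_branch, max_branch))
    b.length = float(rng.uniform(min_branch, max_branch))
    return GeneTree(Node(children=[a, b]))
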