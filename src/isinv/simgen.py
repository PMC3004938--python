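"""Forward simulator for IS-insertion loci on a strain phylogeny.

The generator emulates the kind of multi-strain locus data in which natural
IS inversions were discovered in *Wolbachia*: ~20 strains sequenced at a
locus where an IS5-family element (916 bp, 23-bp asymmetric TIRs, a single
A/T mismatch between the TIR inward reads at np 17, transposase ORF, -35 box
TTGTCC at np 5-10 inside the left TIR, -10 box TATAAT at np 28-33, 17-bp
spacer) inserted once in the ancestor of a monophyletic subset of strains,
duplicating a T(T/A)A target site, and was later inverted in a nested
subclade by one of five mechanisms:

``full_ab``
    whole-element inversion (excision/re-integration in inverted orientation,
    or TIR-TIR recombination with the conversion tract upstream of np 17 —
    indistinguishable at the sequence level);
``internal_c``
    TIR-TIR recombination with the conversion tract downstream of np 17:
    only the transposase gene flips, the TIR configuration stays canonical;
``conversion_left_d``
    the tract covers np 17 and the left TIR templates the conversion: both
    TIR inward reads end up identical to the canonical *left* TIR;
``conversion_right_e``
    as (d) but templated by the right TIR;
``excision``
    precise loss of the element, leaving a single target-site copy.

Point mutations are layered on per branch after event placement
(Jukes-Cantor-style uniform substitutions, no indels beyond the event-level
ones), and every run emits a ground-truth table alongside the alignment.
"""
from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from ._dna import BASES, CODONS, START_CODONS, STOP_CODONS, complement, random_dna, revcomp
from .annotate import detect_tirs, find_transposase_orf, scan_promoters
from .errors import ConfigurationError, MalformedElementError

SCENARIOS = ("full_ab", "internal_c", "conversion_left_d", "conversion_right_e",
             "excision")

DEFAULT_LEFT_TIR = "GGCATTGTCCGATCGCACACCAT"
DEFAULT_RIGHT_TIR = "GGCATTGTCCGATCGCTCACCAT"


@dataclass(frozen=True)
class CanonicalElementSpec:
    """Constrained anatomy of the canonical element.

    All intervals are 1-based inclusive np coordinates relative to the
    element's first nucleotide (the outer end of the left TIR).  The two TIR
    inward reads must differ at exactly ``mismatch_np`` (the diagnostic
    asymmetry on which mechanism classification hinges).
    """

    tir_length: int = 23
    mismatch_np: int = 17
    left_tir_inward: str = DEFAULT_LEFT_TIR
    right_tir_inward: str = DEFAULT_RIGHT_TIR
    orf_length: int = 870
    minus35_np_interval: tuple[int, int] = (5, 10)
    minus35_seq: str = "TTGTCC"
    minus10_np_interval: tuple[int, int] = (28, 33)
    minus10_seq: str = "TATAAT"
    total_length: int = 916

    def validate(self) -> None:
        t = self.tir_length
        if len(self.left_tir_inward) != t or len(self.right_tir_inward) != t:
            raise ConfigurationError("TIR strings must have length tir_length")
        diffs = [i + 1 for i in range(t)
                 if self.left_tir_inward[i] != self.right_tir_inward[i]]
        if diffs != [self.mismatch_np]:
            raise ConfigurationError(
                "left and right TIR inward reads must differ exactly at "
                f"mismatch_np={self.mismatch_np}, got differences at {diffs}"
            )
        if self.orf_length % 3 != 0 or self.orf_length < 6:
            raise ConfigurationError("orf_length must be a positive multiple of 3")
        a35, b35 = self.minus35_np_interval
        a10, b10 = self.minus10_np_interval
        if b35 - a35 + 1 != 6 or b10 - a10 + 1 != 6:
            raise ConfigurationError("promoter boxes must be hexamers")
        if b35 <= t and self.left_tir_inward[a35 - 1 : b35] != self.minus35_seq:
            raise ConfigurationError(
                "-35 box lies inside the left TIR but disagrees with its sequence"
            )
        if self.total_length < 2 * t + 6:
            raise ConfigurationError("total_length too small for two TIRs")
        # ORF may overlap each TIR by at most 3 nt (placement search range).
        if self.orf_length > self.total_length - 2 * t + 6:
            raise ConfigurationError("orf_length too large for the element interior")

    @property
    def spacer(self) -> int:
        return self.minus10_np_interval[0] - self.minus35_np_interval[1] - 1


@dataclass
class SimConfig:
    """One locus-simulation run.  ``seed`` fully determines the output."""

    n_strains: int = 20
    tree: str = "random"  # newick string or "random"
    birth_rate: float = 1.0
    insertion_clade: object = "random"  # list of leaf labels or "random"
    inversion_clade: object = "random"  # nested subset, "random", or None
    scenario: str | None = "conversion_left_d"
    target_site: str = "TTA"
    flank_length: int = 300
    mutation_rate: float = 0.0  # substitutions / site / branch-length unit
    protect_features: bool = True
    seed: int = 0
    locus_id: str = "locus01"

    def validate(self) -> None:
        if self.target_site not in ("TTA", "TAA"):
            raise ConfigurationError("target_site must be TTA or TAA")
        if self.scenario is not None and self.scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if self.mutation_rate < 0:
            raise ConfigurationError("mutation_rate must be non-negative")
        if self.flank_length < 20:
            raise ConfigurationError("flank_length must be at least 20 nt")
        if self.n_strains < 3:
            raise ConfigurationError("need at least 3 strains")


@dataclass
class SimTruth:
    """Ground truth emitted with every simulated locus."""

    locus_id: str
    scenario: str | None
    states: dict  # strain -> "absent" | "canonical" | "inverted"
    events: list  # [{"type": ..., "branch": child-node label}]
    reference_strain: str
    element_interval_alignment: tuple[int, int]
    element_interval_ungapped: tuple[int, int]
    insertion_clade: list
    inversion_clade: list
    tree_newick: str
    target_site: str
    n_substitutions: int = 0
    expected_substitutions: float = 0.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


@dataclass
class LocusSim:
    """A simulated locus: aligned rows plus its truth record."""

    alignment: list  # ordered [(strain_id, aligned_row), ...]
    truth: SimTruth


# ---------------------------------------------------------------------------
# canonical element construction
# ---------------------------------------------------------------------------

def _fixed_template(spec: CanonicalElementSpec) -> list:
    """0-based array of constrained characters (None = free filler)."""
    L, t = spec.total_length, spec.tir_length
    fixed: list = [None] * L

    def place(start0: int, s: str, what: str) -> None:
        for i, c in enumerate(s):
            p = start0 + i
            if p < 0 or p >= L:
                raise ConfigurationError(f"{what} falls outside the element")
            if fixed[p] is not None and fixed[p] != c:
                raise ConfigurationError(
                    f"{what} conflicts with another constrained feature at np {p + 1}"
                )
            fixed[p] = c

    place(0, spec.left_tir_inward, "left TIR")
    place(L - t, revcomp(spec.right_tir_inward), "right TIR")
    place(spec.minus35_np_interval[0] - 1, spec.minus35_seq, "-35 box")
    place(spec.minus10_np_interval[0] - 1, spec.minus10_seq, "-10 box")
    return fixed


def _codon_options(fixed3: list) -> list:
    return [c for c in CODONS
            if c not in STOP_CODONS
            and all(f is None or f == c[i] for i, f in enumerate(fixed3))]


def _place_orf(fixed: list, spec: CanonicalElementSpec) -> tuple[int, int]:
    """Choose the ORF start (0-based) compatible with every fixed feature.

    The ORF must keep the fixed promoter characters stop-free in its frame;
    it may overlap each TIR by at most 3 nt (transposase ORFs commonly run
    into the TIRs).  Writes the chosen start and stop codons into ``fixed``
    and returns the 0-based inclusive interval.
    """
    L, t = spec.total_length, spec.tir_length
    for s0 in range(max(0, t - 3), L - t + 3 - spec.orf_length + 1):
        e0 = s0 + spec.orf_length - 1
        start = next((c for c in START_CODONS
                      if all(fixed[s0 + i] in (None, c[i]) for i in range(3))), None)
        stop = next((c for c in sorted(STOP_CODONS)
                     if all(fixed[e0 - 2 + i] in (None, c[i]) for i in range(3))), None)
        if start is None or stop is None:
            continue
        interior_ok = all(
            _codon_options(fixed[p : p + 3]) for p in range(s0 + 3, e0 - 2, 3)
        )
        if not interior_ok:
            continue
        for i in range(3):
            fixed[s0 + i] = start[i]
            fixed[e0 - 2 + i] = stop[i]
        return s0, e0
    raise ConfigurationError(
        "no ORF placement is compatible with the constrained features"
    )


def _guard_pairs(spec: CanonicalElementSpec, d_max: int = 2) -> list:
    """0-based position pairs that must NOT be complementary.

    Breaking complementarity at the ``d_max`` positions immediately interior
    to each TIR guarantees the terminal repeat is exactly ``tir_length`` long
    (the inverted repeat cannot be extended inward), so the de novo detector
    is unambiguous for every seed.
    """
    L, t = spec.total_length, spec.tir_length
    return [(t + j, L - t - 1 - j) for j in range(d_max)]


def _fill_element(fixed: list, orf: tuple[int, int],
                  spec: CanonicalElementSpec, rng: np.random.Generator) -> str:
    s0, e0 = orf
    chars = list(fixed)
    for p in range(s0 + 3, e0 - 2, 3):
        if any(chars[p + i] is None for i in range(3)):
            options = _codon_options(fixed[p : p + 3])
            codon = options[rng.integers(len(options))]
            chars[p : p + 3] = codon
    for p in range(len(chars)):
        if chars[p] is None:
            chars[p] = BASES[rng.integers(4)]
    for p, q in _guard_pairs(spec):
        if chars[p] == complement(chars[q]):
            movable = q if fixed[q] is None and not (s0 <= q <= e0) else p
            if fixed[movable] is not None or (s0 <= movable <= e0):
                raise ConfigurationError(
                    "cannot break TIR-boundary complementarity: positions fixed"
                )
            banned = complement(chars[p if movable == q else q])
            choices = [b for b in BASES if b != banned]
            chars[movable] = choices[rng.integers(3)]
    return "".join(chars)


def _element_ok(element: str, spec: CanonicalElementSpec,
                orf: tuple[int, int]) -> bool:
    """Generator self-check: the realised element must be unambiguous.

    The designed TIR length, diagnostic mismatch, ORF and promoter pair must
    be exactly what the de novo annotators recover, so the synthetic truth is
    well defined for any seed.
    """
    tirs = detect_tirs(element)
    if tirs is None or tirs.length != spec.tir_length:
        return False
    if list(tirs.mismatch_positions) != [spec.mismatch_np]:
        return False
    found = find_transposase_orf(element)
    if found != ((orf[0] + 1, orf[1] + 1), "+"):
        return False
    hits = scan_promoters(element)
    if not hits:
        return False
    top = hits[0]
    return (top.minus35_interval == spec.minus35_np_interval
            and top.minus10_interval == spec.minus10_np_interval)


def build_canonical_element(spec: CanonicalElementSpec, seed: int) -> str:
    """Construct one canonical element top strand honouring the spec.

    Constrained features (TIRs, promoter boxes, ORF start/stop and frame) are
    deterministic; interior filler is random under ``seed``, resampled until
    the element passes the generator self-checks (exact TIR length, unique
    top-ranked promoter pair, the designed ORF as the longest ORF).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    fixed = _fixed_template(spec)
    orf = _place_orf(fixed, spec)
    for _ in range(200):
        element = _fill_element(fixed, orf, spec, rng)
        if _element_ok(element, spec, orf):
            return element
    raise ConfigurationError(
        "could not realise an element satisfying the generator guarantees"
    )


# ---------------------------------------------------------------------------
# inversion operators
# ---------------------------------------------------------------------------

def apply_inversion_operator(element: str, spec: CanonicalElementSpec,
                             scenario: str) -> str:
    """Apply one inversion/excision operator to a canonical element.

    ``full_ab``: reverse complement of the whole element.
    ``internal_c``: reverse complement of np ``mismatch_np+1 .. len-mismatch_np``
    (the breakpoint sits in the np 18-23 tract, where any position yields the
    same observable TIR configuration because that tract is identical between
    the TIRs).  ``conversion_left_d`` / ``conversion_right_e``: the internal
    inversion plus homogenisation of both TIR inward reads to the left /
    right canonical read.  ``excision``: the element is removed (the caller
    keeps a single target-site copy).
    """
    if scenario not in SCENARIOS:
        raise ConfigurationError(f"unknown scenario {scenario!r}")
    if scenario == "excision":
        return ""
    t = spec.tir_length
    if len(element) < 2 * t:
        raise MalformedElementError(
            f"element of {len(element)} nt cannot carry two {t}-nt TIRs"
        )
    if scenario == "full_ab":
        return revcomp(element)
    m = spec.mismatch_np
    inner = element[:m] + revcomp(element[m : len(element) - m]) + element[len(element) - m:]
    if scenario == "internal_c":
        return inner
    template = (spec.left_tir_inward if scenario == "conversion_left_d"
                else spec.right_tir_inward)
    return template + inner[t:-t] + revcomp(template)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def _yule_newick(n: int, rng: np.random.Generator, birth_rate: float = 1.0) -> str:
    """Random Yule (pure-birth) tree, height normalised to 1.0."""

    class _N:
        __slots__ = ("children", "start", "length", "label")

        def __init__(self, start):
            self.children = []
            self.start = start
            self.length = 0.0
            self.label = None

    root = _N(0.0)
    active = [_N(0.0), _N(0.0)]
    root.children = list(active)
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        parent.length = t - parent.start
        kids = [_N(t), _N(t)]
        parent.children = kids
        active.extend(kids)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for leaf in active:
        leaf.length = t - leaf.start
    height = t if t > 0 else 1.0

    counter = [0]

    def render(node) -> str:
        if not node.children:
            counter[0] += 1
            return f"s{counter[0]:02d}:{node.length / height:.6f}"
        inside = ",".join(render(c) for c in node.children)
        return f"({inside}):{node.length / height:.6f}"

    inside = ",".join(render(c) for c in root.children)
    return f"({inside});"


def _prepare_tree(config: SimConfig, rng: np.random.Generator) -> dendropy.Tree:
    if config.tree == "random":
        newick = _yule_newick(config.n_strains, rng, config.birth_rate)
    else:
        newick = config.tree
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(leaves)) != len(leaves):
        raise ConfigurationError("duplicate leaf labels in tree")
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.label = node.taxon.label
        elif node.label is None:
            i += 1
            node.label = f"n{i:02d}"
    return tree


def _leafset(node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _pick_clades(tree: dendropy.Tree, config: SimConfig,
                 rng: np.random.Generator):
    """Resolve insertion/inversion clades to tree nodes."""
    all_leaves = _leafset(tree.seed_node)
    nodes = list(tree.preorder_node_iter())

    if config.insertion_clade == "random":
        candidates = [nd for nd in nodes
                      if not nd.is_leaf() and nd is not tree.seed_node
                      and 2 <= len(_leafset(nd)) <= len(all_leaves) - 1]
        if not candidates:
            raise ConfigurationError("tree has no internal proper-subset clade")
        ins = candidates[int(rng.integers(len(candidates)))]
    else:
        want = frozenset(config.insertion_clade)
        ins = next((nd for nd in nodes if _leafset(nd) == want), None)
        if ins is None:
            raise ConfigurationError(
                f"insertion clade {sorted(want)} is not monophyletic in the tree"
            )

    inv = None
    if config.scenario is not None:
        if config.inversion_clade == "random":
            candidates = [nd for nd in ins.preorder_iter()
                          if nd is not ins and len(_leafset(nd)) < len(_leafset(ins))]
            internal = [nd for nd in candidates if not nd.is_leaf()]
            pool = internal or candidates
            if not pool:
                raise ConfigurationError("insertion clade too small to nest an inversion")
            inv = pool[int(rng.integers(len(pool)))]
        else:
            want = frozenset(config.inversion_clade)
            if not want <= _leafset(ins):
                raise ConfigurationError(
                    "inversion_clade must be a subset of insertion_clade"
                )
            inv = next((nd for nd in ins.preorder_iter() if _leafset(nd) == want),
                       None)
            if inv is None:
                raise ConfigurationError(
                    f"inversion clade {sorted(want)} is not monophyletic"
                )
    return ins, inv


# ---------------------------------------------------------------------------
# locus simulation
# ---------------------------------------------------------------------------

@dataclass
class _Segments:
    """A lineage's locus sequence, kept as structured segments."""

    lf: str
    tsd1: str
    element: str | None
    tsd2: str | None
    rf: str
    state: str = "absent"


def _element_protect_mask(spec: CanonicalElementSpec) -> np.ndarray:
    """Boolean mask of element positions shielded from point mutations.

    Protects both TIRs plus the boundary guard positions just inside them
    (which pin the TIR length), both promoter boxes and their mirror images
    (the boxes move to mirrored np after an internal inversion), so the
    diagnostic configuration is never destroyed in validation fixtures.
    """
    L, t = spec.total_length, spec.tir_length
    mask = np.zeros(L, dtype=bool)
    mask[: t + 2] = True
    mask[L - t - 2:] = True
    for a, b in (spec.minus35_np_interval, spec.minus10_np_interval):
        mask[a - 1 : b] = True
        mask[L - b : L - a + 1] = True
    return mask


def _mutate(seg: str, p: float, rng: np.random.Generator,
            mask: np.ndarray | None) -> tuple[str, int, int]:
    """Substitute each unprotected site with prob ``p``; returns
    (sequence, n_substitutions, n_mutable_sites)."""
    n = len(seg)
    if n == 0:
        return seg, 0, 0
    mutable = np.ones(n, dtype=bool) if mask is None else ~mask[:n]
    n_mutable = int(mutable.sum())
    hit = (rng.random(n) < p) & mutable
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return seg, 0, n_mutable
    chars = list(seg)
    for i in idx:
        others = [b for b in BASES if b != chars[i]]
        chars[i] = others[rng.integers(3)]
    return "".join(chars), int(idx.size), n_mutable


def simulate_locus(config: SimConfig,
                   spec: CanonicalElementSpec | None = None) -> LocusSim:
    """Simulate one locus alignment with ground truth.

    Strains outside the insertion clade carry the two flanks joined by a
    single target-site copy; strains inside carry TSD + element + TSD, with
    the configured scenario applied in the nested inversion clade.  Absence
    is encoded in the alignment as one contiguous gap block spanning the
    element plus the second TSD copy.  Point mutations are applied per branch
    (probability ``mutation_rate * branch_length`` per site) after event
    placement.  The same config and seed always yield byte-identical output.
    """
    spec = spec or CanonicalElementSpec()
    config.validate()
    spec.validate()
    rng = np.random.default_rng(config.seed)
    element = build_canonical_element(spec, int(rng.integers(2**31)))
    tree = _prepare_tree(config, rng)
    ins_node, inv_node = _pick_clades(tree, config, rng)

    site = config.target_site
    ancestral = _Segments(
        lf=random_dna(config.flank_length, rng),
        tsd1=site,
        element=None,
        tsd2=None,
        rf=random_dna(config.flank_length, rng),
    )

    elem_mask = _element_protect_mask(spec) if config.protect_features else None
    tsd_mask_protect = config.protect_features
    events: list = []
    n_subs = 0
    expected_subs = 0.0
    states: dict = {}

    node_state: dict = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            st = copy.copy(ancestral)
        else:
            st = copy.copy(node_state[id(node.parent_node)])
        if node is ins_node:
            st.element = element
            st.tsd2 = site
            st.state = "canonical"
            events.append({"type": "insertion", "branch": node.label})
        if inv_node is not None and node is inv_node:
            if config.scenario == "excision":
                st.element = None
                st.tsd2 = None
                st.state = "absent"
            else:
                st.element = apply_inversion_operator(st.element, spec,
                                                      config.scenario)
                st.state = "inverted"
            events.append({"type": config.scenario, "branch": node.label})
        blen = node.edge.length if node.edge.length is not None else 1.0
        if node.parent_node is not None and config.mutation_rate > 0:
            p = config.mutation_rate * blen
            if p > 1:
                raise ConfigurationError(
                    "mutation_rate * branch length exceeds 1 substitution/site"
                )
            full_tsd = np.ones(len(site), dtype=bool) if tsd_mask_protect else None
            for name in ("lf", "tsd1", "element", "tsd2", "rf"):
                seg = getattr(st, name)
                if seg is None:
                    continue
                mask = {"element": elem_mask, "tsd1": full_tsd,
                        "tsd2": full_tsd}.get(name)
                seg2, k, n_mut = _mutate(seg, p, rng, mask)
                setattr(st, name, seg2)
                n_subs += k
                expected_subs += p * n_mut
        node_state[id(node)] = st

    # assemble the alignment in leaf-encounter (preorder) order
    gap_block = "-" * (len(element) + len(site))
    col_start = config.flank_length + len(site) + 1
    col_end = col_start + len(element) - 1
    alignment = []
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            continue
        st = node_state[id(node)]
        states[node.label] = st.state
        if st.element is None:
            row = st.lf + st.tsd1 + gap_block + st.rf
        else:
            row = st.lf + st.tsd1 + st.element + st.tsd2 + st.rf
        alignment.append((node.label, row))

    reference = next((s for s, _ in alignment if states[s] == "canonical"), None)
    if reference is None:
        raise ConfigurationError(
            "no strain retains a canonical element to serve as reference"
        )

    truth = SimTruth(
        locus_id=config.locus_id,
        scenario=config.scenario,
        states=states,
        events=events,
        reference_strain=reference,
        element_interval_alignment=(col_start, col_end),
        element_interval_ungapped=(col_start, col_end),
        insertion_clade=sorted(_leafset(ins_node)),
        inversion_clade=sorted(_leafset(inv_node)) if inv_node is not None else [],
        tree_newick=tree.as_string(schema="newick",
                                   suppress_rooting=True).strip(),
        target_site=site,
        n_substitutions=n_subs,
        expected_substitutions=expected_subs,
    )
    return LocusSim(alignment=alignment, truth=truth)


def simulate_batch(n_loci: int, n_with_inversion: int, seed: int,
                   base_config: SimConfig | None = None,
                   spec: CanonicalElementSpec | None = None,
                   scenario: str = "conversion_left_d") -> list[LocusSim]:
    """Simulate a panel of loci on one shared strain tree.

    ``n_with_inversion`` of the loci receive a nested inversion event with
    the given scenario; the rest carry only the canonical insertion.  The
    shared tree mirrors a real survey where all loci are sequenced from the
    same strain panel.
    """
    if not 0 <= n_with_inversion <= n_loci:
        raise ConfigurationError("n_with_inversion must lie in [0, n_loci]")
    base = base_config or SimConfig()
    rng = np.random.default_rng(seed)
    tree_newick = (_yule_newick(base.n_strains, rng, base.birth_rate)
                   if base.tree == "random" else base.tree)
    which = set(rng.choice(n_loci, size=n_with_inversion, replace=False).tolist())
    sims = []
    for i in range(n_loci):
        cfg = dataclasses.replace(
            base,
            tree=tree_newick,
            locus_id=f"locus{i + 1:02d}",
            scenario=scenario if i in which else None,
            inversion_clade="random" if i in which else None,
            seed=int(rng.integers(2**31)),
        )
        sims.append(simulate_locus(cfg, spec))
    return sims


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_locus(sim: LocusSim, out_dir) -> Path:
    """Write one locus as aligned FASTA plus a JSON truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / f"{sim.truth.locus_id}.fasta"
    with open(fasta, "w") as fh:
        for strain, row in sim.alignment:
            fh.write(f">{strain}\n{row}\n")
    with open(f"{fasta}.json", "w") as fh:
        fh.write(sim.truth.to_json())
    return fasta


def write_batch(sims: list, out_dir) -> None:
    """Write a locus panel: FASTAs, sidecars, shared tree, truth TSV, events."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sim in sims:
        write_locus(sim, out_dir)
    with open(out_dir / "tree.nwk", "w") as fh:
        fh.write(sims[0].truth.tree_newick + "\n")
    with open(out_dir / "truth.tsv", "w") as fh:
        fh.write("strain\tlocus\tstate\tscenario\n")
        for sim in sims:
            for strain, state in sim.truth.states.items():
                fh.write(f"{strain}\t{sim.truth.locus_id}\t{state}\t"
                         f"{sim.truth.scenario or 'none'}\n")
    with open(out_dir / "events.json", "w") as fh:
        json.dump({sim.truth.locus_id: sim.truth.events for sim in sims},
                  fh, indent=1)
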