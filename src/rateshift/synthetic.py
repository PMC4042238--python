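"""Synthetic data for every stage of the locus analysis.

Three generators:

* ``simulate_locus`` — gap-free orthologous sequences over the fixed
  four-taxon tree (((mouse, rat), human), dog) under JC69, with
  piecewise-constant rate multipliers switching at an inversion
  changepoint (on the rodent stem) and a gene-birth changepoint (on the
  mouse terminal branch), plus constant-rate reference sequences.  The
  changepoints are placed so that the expected path-integrated distance
  of every species pair equals the rate model's forward equations
  exactly; raw per-branch expected path lengths are exposed for users
  who want other conventions.
* ``make_block_fixture`` / ``make_locus_blocks_fixture`` — toy chains of
  MAF-style alignment blocks with planted strand-flipped (inverted)
  segments.
* ``make_te_fixture`` / ``make_feature_fixture`` — a curated
  transposable-element table (eleven ancestral elements A-K shared by at
  least two species including mouse, plus single-species decoys) and the
  exon/intron map of the antisense lncRNA pair they decorate.

All randomness flows from a single integer seed; identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .alignments import MultipleAlignment, write_fasta
from .ratemodel import NormalizedRates
from .regionmap import AlignmentBlock, FeatureInterval, SpeciesAnchor, TEAnnotation

TAXA = ("mouse", "rat", "human", "dog")
BRANCHES = ("hr_ancestor", "human", "rodent_stem", "mouse", "rat", "dog")
_ALPHABET = np.frombuffer(b"ACGT", dtype="S1")

BirthPlacement = Literal["mouse", "symmetric"]


class ParameterError(ValueError):
    """Rate/timing parameters outside the model's feasible region."""


@dataclass(frozen=True)
class SpeciesTree:
    """Fixed topology (((mouse, rat), human), dog) with ultrametric times.

    ``t_mr`` < ``t_hr`` < ``t_hd`` are the pairwise divergence times
    (time units are arbitrary; only products rate x time matter).
    """

    t_mr: float = 0.05
    t_hr: float = 0.2
    t_hd: float = 0.25
    taxa: tuple[str, ...] = TAXA

    def __post_init__(self) -> None:
        if not 0 < self.t_mr < self.t_hr < self.t_hd:
            raise ParameterError(
                f"divergence times must satisfy 0 < t_MR < t_HR < t_HD; "
                f"got ({self.t_mr}, {self.t_hr}, {self.t_hd})"
            )

    @property
    def newick(self) -> str:
        return (
            f"(((mouse:{self.t_mr},rat:{self.t_mr}):{self.t_hr - self.t_mr},"
            f"human:{self.t_hr}):{self.t_hd - self.t_hr},dog:{self.t_hd});"
        )


@dataclass(frozen=True)
class RateParams:
    """Stage rates (substitutions/site/time) and event-timing fractions.

    r0 applies before the inversion, r1 between inversion and gene
    birth, r2 afterwards; r_ref is the single reference rate.  k1 is the
    fraction of t_HR elapsed since the inversion (the inversion sits
    (1-k1)*t_HR before present, and must fall on the rodent stem); k2 is
    the fraction of t_MR elapsed since gene birth.
    """

    r0: float
    r1: float
    r2: float
    r_ref: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        for name in ("r0", "r1", "r2", "r_ref"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("k1", "k2"):
            if not 0 < getattr(self, name) < 1:
                raise ParameterError(f"{name} must lie strictly in (0, 1)")

    def check_feasible(self, tree: SpeciesTree) -> None:
        """The inversion changepoint (1-k1)*t_HR must sit on the rodent stem."""
        t1 = (1 - self.k1) * tree.t_hr
        if not tree.t_mr <= t1 <= tree.t_hr:
            raise ParameterError(
                f"inversion changepoint {t1:.4g} off the rodent stem "
                f"[{tree.t_mr}, {tree.t_hr}]: k1 = {self.k1} infeasible "
                f"(need k1 <= {1 - tree.t_mr / tree.t_hr:.4g})"
            )


@dataclass
class SimulatedLocus:
    test_alignment: MultipleAlignment
    ref_alignment: MultipleAlignment
    tree: SpeciesTree
    params: RateParams
    seed: int
    birth_placement: BirthPlacement = "mouse"


# ---------------------------------------------------------------------------
# Analytic branch path lengths (expected substitutions per site)


def stage_branch_lengths(
    tree: SpeciesTree, params: RateParams, birth_placement: BirthPlacement = "mouse"
) -> dict[str, float]:
    """Per-branch expected substitutions/site for the test region.

    With the gene-birth rate change on the mouse branch only (default),
    the pairwise path sums reproduce the forward model exactly:
    HD = 2 r0 t_HD, HR = (1+k1) r0 t_HR + (1-k1) r1 t_HR,
    MR = (1+k2) r1 t_MR + (1-k2) r2 t_MR.  The ``symmetric`` placement
    splits the post-birth segment across both rodent tips (same MR sum,
    but it leaks an r2 segment into the HR path).
    """
    params.check_feasible(tree)
    r0, r1, r2, k1, k2 = params.r0, params.r1, params.r2, params.k1, params.k2
    t1 = (1 - k1) * tree.t_hr  # inversion, time before present
    bl = {
        "hr_ancestor": r0 * (tree.t_hd - tree.t_hr),
        "human": r0 * tree.t_hr,
        "dog": r0 * tree.t_hd,
        "rodent_stem": r0 * (tree.t_hr - t1) + r1 * (t1 - tree.t_mr),
    }
    if birth_placement == "mouse":
        t2 = (1 - k2) * tree.t_mr
        bl["mouse"] = r1 * (tree.t_mr - t2) + r2 * t2
        bl["rat"] = r1 * tree.t_mr
    elif birth_placement == "symmetric":
        t2 = (1 - k2) * tree.t_mr / 2
        bl["mouse"] = bl["rat"] = r1 * (tree.t_mr - t2) + r2 * t2
    else:
        raise ValueError(f"unknown birth_placement {birth_placement!r}")
    return bl


def ref_branch_lengths(tree: SpeciesTree, r_ref: float) -> dict[str, float]:
    return {
        "hr_ancestor": r_ref * (tree.t_hd - tree.t_hr),
        "human": r_ref * tree.t_hr,
        "dog": r_ref * tree.t_hd,
        "rodent_stem": r_ref * (tree.t_hr - tree.t_mr),
        "mouse": r_ref * tree.t_mr,
        "rat": r_ref * tree.t_mr,
    }


def pair_path_lengths(branch_lengths: dict[str, float]) -> dict[str, float]:
    """Path-integrated distance per species pair (HD, HR, MR)."""
    bl = branch_lengths
    return {
        "HD": bl["human"] + bl["hr_ancestor"] + bl["dog"],
        "HR": bl["human"] + bl["rodent_stem"] + bl["rat"],
        "MR": bl["mouse"] + bl["rat"],
    }


def expected_normalized_rates(
    tree: SpeciesTree, params: RateParams, birth_placement: BirthPlacement = "mouse"
) -> NormalizedRates:
    """Analytic normalized rates implied by the simulation parameters."""
    test = pair_path_lengths(stage_branch_lengths(tree, params, birth_placement))
    ref = pair_path_lengths(ref_branch_lengths(tree, params.r_ref))
    return NormalizedRates(*(test[k] / ref[k] for k in ("HD", "HR", "MR")))


# ---------------------------------------------------------------------------
# Sequence simulation


def _evolve_jc69(seq: np.ndarray, length: float, rng: np.random.Generator) -> np.ndarray:
    """One JC69 branch: each site substitutes with p = 3/4 (1 - e^{-4L/3})
    and, if it does, moves to one of the other three bases uniformly."""
    p = 0.75 * -np.expm1(-4.0 * length / 3.0)
    out = seq.copy()
    hit = rng.random(seq.size) < p
    n_hit = int(hit.sum())
    if n_hit:
        out[hit] = (out[hit] + rng.integers(1, 4, n_hit, dtype=np.uint8)) % 4
    return out


def _simulate_alignment(
    branch_lengths: dict[str, float], length: int, rng: np.random.Generator
) -> MultipleAlignment:
    root = rng.integers(0, 4, length, dtype=np.uint8)
    hr_node = _evolve_jc69(root, branch_lengths["hr_ancestor"], rng)
    mr_node = _evolve_jc69(hr_node, branch_lengths["rodent_stem"], rng)
    tips = {
        "mouse": _evolve_jc69(mr_node, branch_lengths["mouse"], rng),
        "rat": _evolve_jc69(mr_node, branch_lengths["rat"], rng),
        "human": _evolve_jc69(hr_node, branch_lengths["human"], rng),
        "dog": _evolve_jc69(root, branch_lengths["dog"], rng),
    }
    return MultipleAlignment(
        {sp: _ALPHABET[arr].tobytes().decode() for sp, arr in tips.items()}
    )


def simulate_alignment_on_branches(
    branch_lengths: dict[str, float], length: int, seed: int
) -> MultipleAlignment:
    """Escape hatch: simulate directly from per-branch expected path lengths."""
    missing = set(BRANCHES) - set(branch_lengths)
    if missing:
        raise ParameterError(f"missing branch lengths: {sorted(missing)}")
    if length < 1:
        raise ParameterError("length must be >= 1")
    return _simulate_alignment(branch_lengths, length, np.random.default_rng(seed))


def simulate_locus(
    tree: SpeciesTree,
    params: RateParams,
    length_test: int,
    length_ref: int,
    seed: int,
    birth_placement: BirthPlacement = "mouse",
) -> SimulatedLocus:
    """Simulate the test region and its constant-rate reference."""
    if length_test < 1 or length_ref < 1:
        raise ParameterError("alignment lengths must be >= 1")
    bl_test = stage_branch_lengths(tree, params, birth_placement)
    bl_ref = ref_branch_lengths(tree, params.r_ref)
    rng = np.random.default_rng(seed)
    test = _simulate_alignment(bl_test, length_test, rng)
    ref = _simulate_alignment(bl_ref, length_ref, rng)
    for aln in (test, ref):
        aln.meta["seed"] = seed
    return SimulatedLocus(test, ref, tree, params, seed, birth_placement)


def write_locus(locus: SimulatedLocus, out_dir: str | Path) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    test_path, ref_path = out / "test.fasta", out / "reference.fasta"
    write_fasta(locus.test_alignment, test_path)
    write_fasta(locus.ref_alignment, ref_path)
    return test_path, ref_path


#: Reported normalized average rates (HD, HR, MR) of the locus's two
#: conserved elements, and a fixed feasible event timing at which the
#: forward model is inverted to obtain simulable stage rates.  CE1 lies
#: inside the inversion (rate reduced afterwards: HD > HR); CE2 does not
#: (opposite tendency).  CE2's ratios admit positive stage rates only for
#: small k (for k2 >~ 0.06 the implied post-birth rate goes negative),
#: hence the earlier assumed timing.
CONSERVED_ELEMENT_TARGETS: dict[str, tuple[NormalizedRates, float, float]] = {
    "CE1": (NormalizedRates(2.5971, 2.0603, 1.406), 0.2, 0.2),
    "CE2": (NormalizedRates(1.6694, 2.1832, 1.5047), 0.05, 0.05),
}


def conserved_element_params(name: str, r_ref: float = 1.0) -> RateParams:
    """Synthetic stand-in parameters for a curated conserved-element
    alignment: stage rates are the algebraic inversion of the element's
    reported normalized rates at the fixed timing above, so a locus
    simulated with them reproduces those ratios in expectation."""
    from .ratemodel import solve_rate_ratios

    try:
        target, k1, k2 = CONSERVED_ELEMENT_TARGETS[name]
    except KeyError:
        raise KeyError(f"unknown element {name!r}; expected CE1 or CE2") from None
    sol = solve_rate_ratios(target, k1, k2)
    if not sol.feasible:
        raise ParameterError(f"{name}: no positive stage rates at k=({k1}, {k2})")
    return RateParams(
        r0=sol.rho0 * r_ref, r1=sol.rho1 * r_ref, r2=sol.rho2 * r_ref,
        r_ref=r_ref, k1=k1, k2=k2,
    )


def simulate_conserved_element(
    name: str,
    length_test: int = 100_000,
    length_ref: int = 100_000,
    seed: int = 0,
    tree: SpeciesTree | None = None,
) -> SimulatedLocus:
    """Simulate the synthetic stand-in locus for CE1 or CE2."""
    return simulate_locus(
        tree or SpeciesTree(), conserved_element_params(name), length_test, length_ref, seed
    )


# ---------------------------------------------------------------------------
# Alignment-block fixtures


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _ALPHABET[rng.integers(0, 4, n)].tobytes().decode()


def make_block_fixture(
    n_blocks: int,
    inverted_indices: set[int] | Sequence[int],
    seed: int,
    reference: str = "mouse",
    query: str = "rat",
    block_len: int = 200,
    gap: int = 300,
    ref_chrom: str = "chr1",
) -> list[AlignmentBlock]:
    """A colinear chain of blocks with the requested blocks strand-flipped
    on the query species."""
    inverted = set(inverted_indices)
    bad = inverted - set(range(n_blocks))
    if bad:
        raise IndexError(f"inverted indices out of range: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    src_size = 1_000_000
    blocks = []
    pos = 1000
    for i in range(n_blocks):
        text = _random_dna(rng, block_len)
        strand = "-" if i in inverted else "+"
        anchors = {
            reference: SpeciesAnchor(ref_chrom, pos, pos + block_len, "+", src_size, text),
            query: SpeciesAnchor("chrQ", pos, pos + block_len, strand, src_size, text),
        }
        blocks.append(AlignmentBlock(anchors, reference))
        pos += block_len + gap
    return blocks


def make_locus_blocks_fixture(seed: int = 0) -> tuple[list[AlignmentBlock], list[tuple[int, int]]]:
    """A toy whole-locus block chain over mouse chr14 [1000, 10000).

    Human and dog anchors are strand-flipped inside the two planted
    inversion intervals (the ~800 bp one spanning the antisense gene's
    first exon, and the one overlapping its last exon); rat shares the
    mouse orientation throughout, as both rearrangements predate the
    mouse-rat split.  Returns (blocks, planted inversion intervals).
    """
    inversions = [(2050, 2850), (9000, 9600)]
    breakpoints = [1000, 2050, 2850, 9000, 9600, 10000]
    rng = np.random.default_rng(seed)
    src_size = 1_000_000
    blocks = []
    for seg_start, seg_end in zip(breakpoints[:-1], breakpoints[1:]):
        flipped = any(s <= seg_start and seg_end <= e for s, e in inversions)
        n_sub = max(1, (seg_end - seg_start) // 900)
        edges = np.linspace(seg_start, seg_end, n_sub + 1).astype(int)
        for a, b in zip(edges[:-1], edges[1:]):
            text = _random_dna(rng, int(b - a))
            anchors = {
                "mouse": SpeciesAnchor("chr14", int(a), int(b), "+", src_size, text),
                "rat": SpeciesAnchor("chr15", int(a), int(b), "+", src_size, text),
                "human": SpeciesAnchor(
                    "chr10", int(a), int(b), "-" if flipped else "+", src_size, text
                ),
                "dog": SpeciesAnchor(
                    "chr4", int(a), int(b), "-" if flipped else "+", src_size, text
                ),
            }
            blocks.append(AlignmentBlock(anchors, "mouse"))
    return blocks, inversions


# ---------------------------------------------------------------------------
# TE and feature fixtures


_LOCUS_CHROM = "chr14"

#: Curated ancestral TE table: symbol, repeat name, class, species, interval.
_ANCESTRAL_TES: list[tuple[str, str, str, tuple[str, ...], tuple[int, int]]] = [
    ("A", "MIR", "SINE", ("mouse", "rat", "human", "dog"), (1400, 1600)),
    ("B", "MIR", "SINE", ("mouse", "rat", "human", "dog"), (2400, 2600)),
    ("C", "Chap1_Mam", "DNA", ("mouse", "human"), (2900, 3000)),
    ("D", "MER91A", "DNA", ("mouse", "rat", "human", "dog"), (3900, 4100)),
    ("E", "URR1B", "DNA", ("mouse", "rat"), (6700, 6900)),
    ("F", "MTEb", "LTR", ("mouse", "rat"), (7200, 7400)),
    ("G", "MIR3", "SINE", ("mouse", "rat", "human"), (8100, 8200)),
    ("H", "MT2B2", "LTR", ("mouse", "rat"), (8300, 8400)),
    ("I", "B1F", "SINE", ("mouse", "rat"), (8500, 8600)),
    ("J", "PB1D10", "SINE", ("mouse", "rat"), (8700, 8800)),
    ("K", "L1MD3", "LINE", ("mouse", "human", "dog"), (8900, 9100)),
]

_RAW_CLASS = {"SINE": "SINE/MIR", "LINE": "LINE/L1", "DNA": "DNA/hAT-Charlie", "LTR": "LTR/ERVL-MaLR"}


def make_te_fixture(exon5_reading: Literal["J", "I"] = "J") -> list[TEAnnotation]:
    """Per-species TE records for the eleven shared ancestral elements
    plus two single-species decoys (one mouse-only, one rat-only).

    ``exon5_reading`` controls the identity of the fourth element in the
    last exon: ``"J"`` keeps the distinct PB1D10 element; ``"I"`` labels
    it as a second copy of the B1F element instead (the two readings of
    an ambiguous published composition table).
    """
    records: list[TEAnnotation] = []
    for symbol, name, cls, species, (start, end) in _ANCESTRAL_TES:
        if symbol == "J" and exon5_reading == "I":
            symbol, name = "I", "B1F"
        for sp in species:
            records.append(
                TEAnnotation(
                    name=name,
                    repeat_class=cls,
                    species=sp,
                    chrom=_LOCUS_CHROM,
                    start=start,
                    end=end,
                    symbol=symbol,
                    raw_class=_RAW_CLASS[cls],
                )
            )
    # decoys: present in a single species, hence removed by the shared filter
    records.append(
        TEAnnotation("B1_Mus1", "SINE", "mouse", _LOCUS_CHROM, 10500, 10600, raw_class="SINE/Alu")
    )
    records.append(
        TEAnnotation("ID_Rn1", "SINE", "rat", _LOCUS_CHROM, 10700, 10800, raw_class="SINE/ID")
    )
    return records


def make_feature_fixture() -> list[FeatureInterval]:
    """Exon/intron map of the overlapping antisense lncRNA pair on the toy
    locus: the sense gene has 3 exons / 2 introns, the antisense gene 5
    exons / 4 introns; coordinates are consistent with the TE fixture."""
    c = _LOCUS_CHROM
    return [
        FeatureInterval("Pldi.exon1", c, 1000, 1200),
        FeatureInterval("Pldi.intron1", c, 1200, 5000),
        FeatureInterval("Pldi.exon2", c, 5000, 5200),
        FeatureInterval("Pldi.intron2", c, 5200, 5700),
        FeatureInterval("Pldi.exon3", c, 5700, 6000),
        FeatureInterval("Ak158810.exon1", c, 2100, 2300, "-"),
        FeatureInterval("Ak158810.intron1", c, 2300, 3500, "-"),
        FeatureInterval("Ak158810.exon2", c, 3500, 3700, "-"),
        FeatureInterval("Ak158810.intron2", c, 3700, 4600, "-"),
        FeatureInterval("Ak158810.exon3", c, 4600, 4900, "-"),
        FeatureInterval("Ak158810.intron3", c, 4900, 6300, "-"),
        FeatureInterval("Ak158810.exon4", c, 6300, 6500, "-"),
        FeatureInterval("Ak158810.intron4", c, 6500, 8000, "-"),
        FeatureInterval("Ak158810.exon5", c, 8000, 9300, "-"),
    ]


def write_te_table(annotations: Sequence[TEAnnotation], path: str | Path) -> None:
    """Write annotations in the RepeatMasker ``.out`` column layout."""
    header = (
        "   SW   perc perc perc  query     position in query     matching"
        "  repeat         position in repeat\n"
        "score   div. del. ins.  sequence  begin  end   (left)   repeat"
        "  class/family   begin end (left) ID\n"
        "\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i, te in enumerate(annotations, start=1):
            fh.write(
                f"{1000 + i:5d}  10.0  0.5  0.5  {te.chrom}  {te.start + 1}  "
                f"{te.end}  (0)  +  {te.name}  {te.raw_class or te.repeat_class}  "
                f"1  {te.end - te.start}  (0)  {i}\n"
            )


# ---------------------------------------------------------------------------
# Transcript fixture


def make_transcript_fixture(total_len: int = 2900, seed: int = 158810) -> str:
    """Synthetic ~2.9 kb lncRNA-like transcript with a planted sense-strand
    ORF architecture: two ~70 aa AUG-initiated upstream frames followed by
    a 105 aa longest ORF, and no other AUG anywhere.

    This is a synthetic stand-in for the real cDNA (which is not bundled):
    outside the three planted AUGs the sequence is built from {A, C, T}
    only, so G occurs solely inside those AUG codons and no further
    sense-strand ORF can start.  It reproduces the transcript's diagnostic
    property — no ORF long enough to suggest protein-coding capacity,
    with upstream AUGs shielding the longest frame — not its sequence.
    """
    rng = np.random.default_rng(seed)
    no_g = np.frombuffer(b"ACT", dtype="S1")
    safe_codons = ["".join(c) for c in product("ACT", repeat=3) if "".join(c) != "TAA"]

    def filler(n: int) -> str:
        return no_g[rng.integers(0, 3, n)].tobytes().decode()

    def orf(n_aa: int) -> str:
        body = "".join(safe_codons[rng.integers(0, len(safe_codons))] for _ in range(n_aa - 1))
        return "ATG" + body + "TAA"

    parts = [filler(300), orf(70), filler(51), orf(72), filler(60), orf(105)]
    tail = total_len - sum(len(p) for p in parts)
    if tail < 0:
        raise ValueError("total_len too short for the planted ORF architecture")
    parts.append(filler(tail))
    return "".join(parts)
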