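"""DNA molecule populations, lesions and damage operations.

Molecules are represented explicitly: a :class:`DuplexMolecule` is a blunt
linear duplex with per-strand nick lists and a list of covalent lesions; a
:class:`StrandSegment` is a single strand (usually produced by denaturation);
a :class:`CrosslinkNetwork` is a set of strands held together by one or more
interstrand crosslinks after denaturation.

All coordinates are 0-based.  Nick positions are offsets *between*
nucleotides, strictly inside ``(0, length)``; lesion positions are nucleotide
offsets in ``[0, length)``.  Fragmentation operations re-home nicks and
lesions by subtracting the fragment start.

Every stochastic operation takes an explicit ``seed`` and draws from a single
``numpy.random.Generator`` created from it, so results are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np

__all__ = [
    "Lesion",
    "DuplexMolecule",
    "StrandSegment",
    "CrosslinkNetwork",
    "MoleculePopulation",
    "PopulationEntry",
    "INTERSTRAND",
    "INTRASTRAND",
    "MONOADDUCT",
    "BEND_KINDS",
    "mbo1_digest",
    "induce_nicks",
    "induce_dsbs",
    "induce_crosslink_damage",
    "apoptotic_fragmentation",
    "denature",
    "is_amplifiable",
    "read_fasta_population",
    "write_jsonl",
    "read_jsonl",
]

INTERSTRAND = "interstrand_crosslink"
INTRASTRAND = "intrastrand_crosslink"
MONOADDUCT = "monoadduct"
LESION_KINDS = (INTERSTRAND, INTRASTRAND, MONOADDUCT)
#: lesion kinds that bend the duplex and retard native migration
BEND_KINDS = (INTRASTRAND, MONOADDUCT)

_DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Lesion:
    """A covalent lesion at a nucleotide offset.

    ``interstrand_crosslink`` lesions bridge both strands and must carry
    ``strand='both'``; the single-strand kinds must name one strand.
    """

    kind: str
    position: int
    strand: str  # 'top' | 'bottom' | 'both'

    def __post_init__(self) -> None:
        if self.kind not in LESION_KINDS:
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.kind == INTERSTRAND and self.strand != "both":
            raise ValueError("interstrand_crosslink lesions must have strand='both'")
        if self.kind != INTERSTRAND and self.strand not in ("top", "bottom"):
            raise ValueError(f"{self.kind} lesions must be on 'top' or 'bottom'")
        if self.position < 0:
            raise ValueError("lesion position must be >= 0")

    @property
    def is_bend(self) -> bool:
        return self.kind in BEND_KINDS


def _check_nicks(nicks: Sequence[int], length: int, name: str) -> tuple[int, ...]:
    nicks = tuple(int(n) for n in nicks)
    if list(nicks) != sorted(set(nicks)):
        raise ValueError(f"{name} must be sorted with no duplicates")
    if nicks and (nicks[0] <= 0 or nicks[-1] >= length):
        raise ValueError(f"{name} must lie strictly inside (0, length)")
    return nicks


@dataclass(frozen=True)
class DuplexMolecule:
    """A linear double-stranded DNA molecule with nicks and lesions."""

    length: int
    sequence: Optional[str] = None
    nicks_top: tuple[int, ...] = ()
    nicks_bottom: tuple[int, ...] = ()
    lesions: tuple[Lesion, ...] = ()
    origin_label: str = ""
    #: set when adduct density is high enough that the duplex is locally
    #: denatured and its strands run the native dimension single-stranded
    denatured: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("duplex length must be >= 1")
        if self.sequence is not None:
            seq = self.sequence.upper()
            if len(seq) != self.length:
                raise ValueError("sequence length does not match length field")
            if not set(seq) <= _DNA_ALPHABET:
                raise ValueError("sequence contains non-ACGT characters")
            object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "nicks_top", _check_nicks(self.nicks_top, self.length, "nicks_top"))
        object.__setattr__(
            self, "nicks_bottom", _check_nicks(self.nicks_bottom, self.length, "nicks_bottom")
        )
        lesions = tuple(sorted(self.lesions, key=lambda l: (l.position, l.strand, l.kind)))
        for les in lesions:
            if not 0 <= les.position < self.length:
                raise ValueError("lesion position outside [0, length)")
        object.__setattr__(self, "lesions", lesions)

    @property
    def total_nucleotides(self) -> int:
        return 2 * self.length

    @property
    def bend_count(self) -> int:
        return sum(1 for l in self.lesions if l.is_bend)

    @property
    def interstrand_count(self) -> int:
        return sum(1 for l in self.lesions if l.kind == INTERSTRAND)


@dataclass(frozen=True)
class StrandSegment:
    """A single DNA strand, typically released by denaturation.

    ``parent_duplex_length`` and ``parent_bend_count`` record the duplex this
    strand belonged to while the native (first) dimension ran;
    ``is_ss_in_d1`` marks strands that were already single-stranded then.
    """

    length: int
    parent_duplex_length: int
    parent_bend_count: int = 0
    is_ss_in_d1: bool = False
    network_id: Optional[int] = None
    sequence: Optional[str] = None
    origin_label: str = ""

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("segment length must be >= 1")
        if self.length > self.parent_duplex_length:
            raise ValueError("segment longer than its parent duplex")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("sequence length does not match length field")

    @property
    def total_nucleotides(self) -> int:
        return self.length


@dataclass(frozen=True)
class CrosslinkNetwork:
    """Strands covalently joined by interstrand crosslinks after denaturation."""

    member_segments: tuple[StrandSegment, ...]

    def __post_init__(self) -> None:
        members = tuple(self.member_segments)
        if len(members) < 2:
            raise ValueError("a crosslink network needs >= 2 member strands")
        object.__setattr__(self, "member_segments", members)

    @property
    def effective_length(self) -> int:
        return sum(s.length for s in self.member_segments)

    @property
    def total_nucleotides(self) -> int:
        return self.effective_length

    @property
    def parent_duplex_length(self) -> int:
        return self.member_segments[0].parent_duplex_length

    @property
    def parent_bend_count(self) -> int:
        return self.member_segments[0].parent_bend_count


Molecule = Union[DuplexMolecule, StrandSegment, CrosslinkNetwork]


@dataclass(frozen=True)
class PopulationEntry:
    molecule: Molecule
    mass_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.mass_weight < 0:
            raise ValueError("mass_weight must be non-negative")


@dataclass
class MoleculePopulation:
    """A weighted collection of molecules."""

    entries: list[PopulationEntry] = field(default_factory=list)
    seed_provenance: str = ""

    def __iter__(self) -> Iterator[PopulationEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def total_mass(self) -> float:
        return float(sum(e.mass_weight for e in self.entries))

    @property
    def total_nucleotides(self) -> int:
        return sum(e.molecule.total_nucleotides for e in self.entries)

    def add(self, molecule: Molecule, mass_weight: float = 1.0) -> None:
        self.entries.append(PopulationEntry(molecule, mass_weight))

    def require_mass(self) -> None:
        if self.total_mass <= 0:
            raise ValueError("population has no mass")


# ---------------------------------------------------------------------------
# fragmentation helpers
# ---------------------------------------------------------------------------


def _split_duplex(mol: DuplexMolecule, cuts: Sequence[int]) -> list[DuplexMolecule]:
    """Split a duplex at the given double-strand cut offsets.

    Nicks strictly inside a fragment and lesions with ``start <= pos < end``
    are inherited with shifted coordinates.  Total nucleotides are conserved.
    """
    cuts = sorted({int(c) for c in cuts if 0 < int(c) < mol.length})
    if not cuts:
        return [mol]
    bounds = [0, *cuts, mol.length]
    out = []
    for start, end in zip(bounds[:-1], bounds[1:]):
        out.append(
            DuplexMolecule(
                length=end - start,
                sequence=None if mol.sequence is None else mol.sequence[start:end],
                nicks_top=tuple(n - start for n in mol.nicks_top if start < n < end),
                nicks_bottom=tuple(n - start for n in mol.nicks_bottom if start < n < end),
                lesions=tuple(
                    replace(l, position=l.position - start)
                    for l in mol.lesions
                    if start <= l.position < end
                ),
                origin_label=mol.origin_label,
                denatured=mol.denatured,
            )
        )
    return out


def _split_segment(seg: StrandSegment, cuts: Sequence[int]) -> list[StrandSegment]:
    cuts = sorted({int(c) for c in cuts if 0 < int(c) < seg.length})
    if not cuts:
        return [seg]
    bounds = [0, *cuts, seg.length]
    return [
        StrandSegment(
            length=end - start,
            parent_duplex_length=end - start,
            parent_bend_count=seg.parent_bend_count,
            is_ss_in_d1=seg.is_ss_in_d1,
            sequence=None if seg.sequence is None else seg.sequence[start:end],
            origin_label=seg.origin_label,
        )
        for start, end in zip(bounds[:-1], bounds[1:])
    ]


def _split_weights(parent_mass: float, children: Sequence[Molecule]) -> list[float]:
    total = sum(c.total_nucleotides for c in children)
    return [parent_mass * c.total_nucleotides / total for c in children]


def _extend(pop: MoleculePopulation, parent_mass: float, children: Sequence[Molecule]) -> None:
    for child, w in zip(children, _split_weights(parent_mass, children)):
        pop.add(child, w)


# ---------------------------------------------------------------------------
# restriction digestion
# ---------------------------------------------------------------------------


def _find_sites(sequence: str, site: str) -> list[int]:
    out, start = [], 0
    while True:
        i = sequence.find(site, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def _blocked(cut: int, site_len: int, lesions: Iterable[Lesion], window: int) -> bool:
    lo, hi = cut - window, cut + site_len + window
    return any(lo <= l.position < hi for l in lesions)


def _sample_cuts_length_mode(
    length: int, p_cut: float, rng: np.random.Generator
) -> list[int]:
    """Sample cut offsets with geometric inter-site distances (mean 1/p_cut)."""
    cuts, pos = [], 0
    while True:
        pos += int(rng.geometric(p_cut))
        if pos >= length:
            return cuts
        cuts.append(pos)


def mbo1_digest(
    pop: MoleculePopulation,
    site: str = "GATC",
    lesion_block_window: int = 4,
    length_mode: bool = False,
    seed: Optional[int] = None,
) -> MoleculePopulation:
    """Digest every molecule at each recognition-site occurrence.

    Cuts are blunt, placed 5' of the site start on the top-strand coordinate.
    A site is skipped when a lesion lies within ``lesion_block_window``
    nucleotides of it.  Both duplexes and single strands are cut.

    With ``length_mode=True`` molecules may omit sequences and cut positions
    are sampled with per-nucleotide probability ``4**-len(site)`` (geometric
    fragment lengths, mean ``4**len(site)``), seeded by ``seed``.
    """
    site = site.upper()
    if not site or not set(site) <= _DNA_ALPHABET:
        raise ValueError("site must be a non-empty string over A/C/G/T")
    rng = np.random.default_rng(seed)
    p_cut = 4.0 ** -len(site)
    out = MoleculePopulation(seed_provenance=f"{pop.seed_provenance};mbo1_digest(seed={seed})")
    for entry in pop:
        mol, mass = entry.molecule, entry.mass_weight
        if isinstance(mol, CrosslinkNetwork):
            out.add(mol, mass)
            continue
        if mol.sequence is not None:
            cuts = [c for c in _find_sites(mol.sequence, site) if c > 0]
        elif length_mode:
            cuts = _sample_cuts_length_mode(mol.length, p_cut, rng)
        else:
            raise ValueError(
                "molecule has no sequence; pass length_mode=True to sample fragment lengths"
            )
        if isinstance(mol, DuplexMolecule):
            cuts = [c for c in cuts if not _blocked(c, len(site), mol.lesions, lesion_block_window)]
            _extend(out, mass, _split_duplex(mol, cuts))
        else:
            _extend(out, mass, _split_segment(mol, cuts))
    return out


# ---------------------------------------------------------------------------
# break induction
# ---------------------------------------------------------------------------


def _unique_positions(rng: np.random.Generator, n: int, lo: int, hi: int) -> list[int]:
    """n distinct integers in [lo, hi), capped at the interval size."""
    span = hi - lo
    n = min(n, span)
    if n <= 0:
        return []
    return sorted(int(p) + lo for p in rng.choice(span, size=n, replace=False))


def induce_nicks(
    pop: MoleculePopulation,
    rate_per_nt: Optional[float] = None,
    recognition: Optional[str] = None,
    strand_mode: str = "both",
    seed: Optional[int] = None,
) -> MoleculePopulation:
    """Add single-strand breaks, either at random (Poisson) or at a
    recognition sequence (nicking-endonuclease mode).

    In rate mode the number of nicks per duplex is Poisson with mean
    ``rate_per_nt * length``; in recognition mode a nick is placed 3' of every
    occurrence of ``recognition`` on the designated strand(s).  Molecule count
    and total nucleotide count are unchanged (nicks are marks, not cuts, on
    duplexes; single strands are split since a nicked strand falls apart).
    """
    if (rate_per_nt is None) == (recognition is None):
        raise ValueError("pass exactly one of rate_per_nt or recognition")
    if rate_per_nt is not None and rate_per_nt < 0:
        raise ValueError("nick rate must be >= 0")
    if strand_mode not in ("top_only", "both"):
        raise ValueError("strand_mode must be 'top_only' or 'both'")
    if recognition is not None:
        recognition = recognition.upper()
        if not set(recognition) <= _DNA_ALPHABET:
            raise ValueError("recognition must be over A/C/G/T")
    rng = np.random.default_rng(seed)
    out = MoleculePopulation(seed_provenance=f"{pop.seed_provenance};induce_nicks(seed={seed})")
    for entry in pop:
        mol, mass = entry.molecule, entry.mass_weight
        if isinstance(mol, DuplexMolecule):
            if rate_per_nt is not None:
                n = int(rng.poisson(rate_per_nt * mol.length))
                positions = _unique_positions(rng, n, 1, mol.length)
                new_top = list(mol.nicks_top)
                new_bottom = list(mol.nicks_bottom)
                for p in positions:
                    target = new_top
                    if strand_mode == "both" and rng.random() < 0.5:
                        target = new_bottom
                    if p not in target:
                        target.append(p)
                out.add(
                    replace(mol, nicks_top=tuple(sorted(new_top)), nicks_bottom=tuple(sorted(new_bottom))),
                    mass,
                )
            else:
                if mol.sequence is None:
                    raise ValueError("recognition mode requires sequences")
                k = len(recognition)
                top = {min(i + k, mol.length - 1) for i in _find_sites(mol.sequence, recognition)}
                top = {p for p in top if 0 < p < mol.length}
                bottom: set[int] = set()
                if strand_mode == "both":
                    rc = _find_sites(mol.sequence, _revcomp(recognition))
                    bottom = {i for i in rc if 0 < i < mol.length}
                out.add(
                    replace(
                        mol,
                        nicks_top=tuple(sorted(set(mol.nicks_top) | top)),
                        nicks_bottom=tuple(sorted(set(mol.nicks_bottom) | bottom)),
                    ),
                    mass,
                )
        elif isinstance(mol, StrandSegment):
            if rate_per_nt is not None:
                n = int(rng.poisson(rate_per_nt * mol.length))
                _extend(out, mass, _split_segment(mol, _unique_positions(rng, n, 1, mol.length)))
            else:
                out.add(mol, mass)
        else:
            out.add(mol, mass)
    return out


def induce_dsbs(
    pop: MoleculePopulation, rate_per_nt: float, seed: Optional[int] = None
) -> MoleculePopulation:
    """Introduce double-strand breaks at Poisson-placed positions."""
    if rate_per_nt < 0:
        raise ValueError("DSB rate must be >= 0")
    rng = np.random.default_rng(seed)
    out = MoleculePopulation(seed_provenance=f"{pop.seed_provenance};induce_dsbs(seed={seed})")
    for entry in pop:
        mol, mass = entry.molecule, entry.mass_weight
        if isinstance(mol, DuplexMolecule):
            n = int(rng.poisson(rate_per_nt * mol.length))
            _extend(out, mass, _split_duplex(mol, _unique_positions(rng, n, 1, mol.length)))
        elif isinstance(mol, StrandSegment):
            n = int(rng.poisson(rate_per_nt * mol.length))
            _extend(out, mass, _split_segment(mol, _unique_positions(rng, n, 1, mol.length)))
        else:
            out.add(mol, mass)
    return out


# ---------------------------------------------------------------------------
# crosslinking agents
# ---------------------------------------------------------------------------

DEFAULT_CROSSLINK_MIX = {INTERSTRAND: 0.05, INTRASTRAND: 0.75, MONOADDUCT: 0.20}


def induce_crosslink_damage(
    pop: MoleculePopulation,
    dose: float,
    lesion_rate_per_nt_per_dose: float = 2e-3,
    mix: Optional[dict[str, float]] = None,
    denaturation_density_threshold: float = 1.0 / 200.0,
    seed: Optional[int] = None,
) -> MoleculePopulation:
    """Add crosslinker lesions (cisplatin/MMC-like).

    Lesion count per duplex is Poisson with mean ``dose * rate * length``;
    kinds are multinomial over ``mix``.  Duplexes whose density of
    non-interstrand lesions exceeds ``denaturation_density_threshold`` are
    flagged locally denatured: their strands run the native dimension
    single-stranded.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    mix = dict(DEFAULT_CROSSLINK_MIX if mix is None else mix)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("mix proportions must sum to 1")
    kinds = list(mix)
    probs = np.array([mix[k] for k in kinds], dtype=float)
    rng = np.random.default_rng(seed)
    out = MoleculePopulation(
        seed_provenance=f"{pop.seed_provenance};induce_crosslink_damage(dose={dose},seed={seed})"
    )
    for entry in pop:
        mol, mass = entry.molecule, entry.mass_weight
        if not isinstance(mol, DuplexMolecule) or dose == 0:
            out.add(mol, mass)
            continue
        n = int(rng.poisson(dose * lesion_rate_per_nt_per_dose * mol.length))
        positions = _unique_positions(rng, n, 0, mol.length)
        new = list(mol.lesions)
        occupied = {(l.position, l.strand) for l in new}
        n_bendish = sum(1 for l in new if l.kind != INTERSTRAND)
        for p in positions:
            kind = kinds[int(rng.choice(len(kinds), p=probs))]
            strand = "both" if kind == INTERSTRAND else ("top" if rng.random() < 0.5 else "bottom")
            if (p, strand) in occupied or (p, "both") in occupied:
                continue
            occupied.add((p, strand))
            new.append(Lesion(kind, p, strand))
            if kind != INTERSTRAND:
                n_bendish += 1
        out.add(
            replace(
                mol,
                lesions=tuple(new),
                denatured=mol.denatured or (n_bendish / mol.length > denaturation_density_threshold),
            ),
            mass,
        )
    return out


def apoptotic_fragmentation(
    pop: MoleculePopulation,
    repeat_length: int = 180,
    core_length: int = 147,
    p_linker_cleave: float = 0.5,
    ssb_in_linker_rate: float = 0.0,
    seed: Optional[int] = None,
) -> MoleculePopulation:
    """Internucleosomal fragmentation: double-strand cuts at linker midpoints.

    Each linker midpoint (every ``repeat_length``) is cleaved independently
    with probability ``p_linker_cleave``; surviving linkers optionally
    acquire nicks at ``ssb_in_linker_rate`` per linker nucleotide.  Fragment
    lengths are multiples of the repeat (boundary fragments excepted).
    """
    if not 0 <= p_linker_cleave <= 1:
        raise ValueError("p_linker_cleave must be in [0, 1]")
    if ssb_in_linker_rate < 0:
        raise ValueError("ssb_in_linker_rate must be >= 0")
    if not repeat_length > core_length >= 0:
        raise ValueError("need repeat_length > core_length >= 0")
    rng = np.random.default_rng(seed)
    linker = repeat_length - core_length
    out = MoleculePopulation(
        seed_provenance=f"{pop.seed_provenance};apoptotic_fragmentation(seed={seed})"
    )
    for entry in pop:
        mol, mass = entry.molecule, entry.mass_weight
        if not isinstance(mol, DuplexMolecule):
            out.add(mol, mass)
            continue
        boundaries = list(range(repeat_length, mol.length, repeat_length))
        cuts = [b for b in boundaries if rng.random() < p_linker_cleave]
        nicks_top, nicks_bottom = list(mol.nicks_top), list(mol.nicks_bottom)
        if ssb_in_linker_rate > 0:
            for b in boundaries:
                if b in cuts:
                    continue
                n = int(rng.poisson(ssb_in_linker_rate * linker))
                lo = max(1, b - linker // 2)
                hi = min(mol.length, b + linker // 2 + 1)
                for p in _unique_positions(rng, n, lo, hi):
                    target = nicks_top if rng.random() < 0.5 else nicks_bottom
                    if p not in target:
                        target.append(p)
        nicked = replace(
            mol, nicks_top=tuple(sorted(nicks_top)), nicks_bottom=tuple(sorted(nicks_bottom))
        )
        _extend(out, mass, _split_duplex(nicked, cuts))
    return out


# ---------------------------------------------------------------------------
# denaturation and the amplifiability oracle
# ---------------------------------------------------------------------------

_network_counter = 0


def _next_network_id() -> int:
    global _network_counter
    _network_counter += 1
    return _network_counter


def _strand_intervals(length: int, nicks: Sequence[int]) -> list[tuple[int, int]]:
    bounds = [0, *nicks, length]
    return list(zip(bounds[:-1], bounds[1:]))


def denature(pop: MoleculePopulation, context: str = "between_dimensions") -> MoleculePopulation:
    """Heat-denature a population.

    Each duplex splits into strand segments at its nick positions.  Strands
    bridged by interstrand crosslinks remain covalently attached and merge
    into a :class:`CrosslinkNetwork`.

    ``context='between_dimensions'`` models in-gel denaturation after the
    native dimension has run: segments keep their parent's native-phase
    identity.  ``context='pre_load'`` models denaturation before loading:
    crosslinked duplexes renature and re-adopt native duplex mobility, while
    crosslink-free duplexes permanently become single strands
    (``is_ss_in_d1=True``).  Already-denatured species pass through, making
    the operation idempotent.
    """
    if context not in ("pre_load", "between_dimensions"):
        raise ValueError("context must be 'pre_load' or 'between_dimensions'")
    out = MoleculePopulation(seed_provenance=f"{pop.seed_provenance};denature({context})")
    for entry in pop:
        mol, mass = entry.molecule, entry.mass_weight
        if not isinstance(mol, DuplexMolecule):
            out.add(mol, mass)
            continue
        bend = mol.bend_count
        has_xl = mol.interstrand_count > 0
        if context == "pre_load":
            ss_flag = not has_xl or mol.denatured
        else:
            ss_flag = mol.denatured

        top_iv = _strand_intervals(mol.length, mol.nicks_top)
        bot_iv = _strand_intervals(mol.length, mol.nicks_bottom)

        def _seg(start: int, end: int, bottom: bool) -> StrandSegment:
            seq = None
            if mol.sequence is not None:
                seq = mol.sequence[start:end]
                if bottom:
                    seq = _revcomp(seq)
            return StrandSegment(
                length=end - start,
                parent_duplex_length=mol.length,
                parent_bend_count=bend,
                is_ss_in_d1=ss_flag,
                sequence=seq,
                origin_label=mol.origin_label,
            )

        segments = [( "top", iv) for iv in top_iv] + [("bottom", iv) for iv in bot_iv]
        # union-find over segments joined by interstrand crosslinks
        parent = list(range(len(segments)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i: int, j: int) -> None:
            parent[find(i)] = find(j)

        def covering(strand: str, p: int) -> int:
            for idx, (s, (a, b)) in enumerate(segments):
                if s == strand and a <= p < b:
                    return idx
            raise AssertionError("lesion position not covered by any segment")

        for les in mol.lesions:
            if les.kind == INTERSTRAND:
                union(covering("top", les.position), covering("bottom", les.position))

        groups: dict[int, list[int]] = {}
        for idx in range(len(segments)):
            groups.setdefault(find(idx), []).append(idx)

        children: list[Molecule] = []
        for members in groups.values():
            if len(members) == 1:
                strand, (a, b) = segments[members[0]]
                children.append(_seg(a, b, strand == "bottom"))
            else:
                nid = _next_network_id()
                # a crosslink nucleates quick renaturation, so networks always
                # keep native duplex mobility even in adduct-dense molecules
                segs = []
                for idx in members:
                    strand, (a, b) = segments[idx]
                    s = _seg(a, b, strand == "bottom")
                    segs.append(replace(s, network_id=nid, is_ss_in_d1=False))
                children.append(CrosslinkNetwork(tuple(segs)))
        _extend(out, mass, children)
    return out


def is_amplifiable(molecule: Molecule) -> bool:
    """False iff the molecule (or its whole network) carries an interstrand
    crosslink: neither strand can then serve as an intact template."""
    if isinstance(molecule, CrosslinkNetwork):
        return False
    if isinstance(molecule, DuplexMolecule):
        return molecule.interstrand_count == 0
    return True


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_fasta_population(path, origin_label: str = "fasta") -> MoleculePopulation:
    """Load duplexes from a FASTA file; mass proportional to length."""
    from Bio import SeqIO

    pop = MoleculePopulation(seed_provenance=f"fasta:{path}")
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        pop.add(
            DuplexMolecule(length=len(seq), sequence=seq, origin_label=origin_label or rec.id),
            mass_weight=float(len(seq)),
        )
    pop.require_mass()
    return pop


def _molecule_to_dict(mol: Molecule) -> dict:
    if isinstance(mol, DuplexMolecule):
        return {
            "type": "duplex",
            "length": mol.length,
            "sequence": mol.sequence,
            "nicks_top": list(mol.nicks_top),
            "nicks_bottom": list(mol.nicks_bottom),
            "lesions": [
                {"kind": l.kind, "position": l.position, "strand": l.strand} for l in mol.lesions
            ],
            "origin_label": mol.origin_label,
            "denatured": mol.denatured,
        }
    if isinstance(mol, StrandSegment):
        return {
            "type": "segment",
            "length": mol.length,
            "parent_duplex_length": mol.parent_duplex_length,
            "parent_bend_count": mol.parent_bend_count,
            "is_ss_in_d1": mol.is_ss_in_d1,
            "network_id": mol.network_id,
            "sequence": mol.sequence,
            "origin_label": mol.origin_label,
        }
    return {"type": "network", "members": [_molecule_to_dict(s) for s in mol.member_segments]}


def _molecule_from_dict(d: dict) -> Molecule:
    t = d["type"]
    if t == "duplex":
        return DuplexMolecule(
            length=d["length"],
            sequence=d.get("sequence"),
            nicks_top=tuple(d.get("nicks_top", ())),
            nicks_bottom=tuple(d.get("nicks_bottom", ())),
            lesions=tuple(Lesion(l["kind"], l["position"], l["strand"]) for l in d.get("lesions", ())),
            origin_label=d.get("origin_label", ""),
            denatured=d.get("denatured", False),
        )
    if t == "segment":
        return StrandSegment(
            length=d["length"],
            parent_duplex_length=d["parent_duplex_length"],
            parent_bend_count=d.get("parent_bend_count", 0),
            is_ss_in_d1=d.get("is_ss_in_d1", False),
            network_id=d.get("network_id"),
            sequence=d.get("sequence"),
            origin_label=d.get("origin_label", ""),
        )
    if t == "network":
        return CrosslinkNetwork(tuple(_molecule_from_dict(m) for m in d["members"]))
    raise ValueError(f"unknown molecule type {t!r}")


def write_jsonl(pop: MoleculePopulation, path) -> None:
    with open(path, "w") as fh:
        for entry in pop:
            rec = _molecule_to_dict(entry.molecule)
            rec["mass_weight"] = entry.mass_weight
            fh.write(json.dumps(rec) + "\n")


def read_jsonl(path) -> MoleculePopulation:
    pop = MoleculePopulation(seed_provenance=f"jsonl:{path}")
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            mass = rec.pop("mass_weight", 1.0)
            pop.add(_molecule_from_dict(rec), mass)
    return pop
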