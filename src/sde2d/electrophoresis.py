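"""Migration model, gel rendering and experiment scenarios.

Axis convention: the well is at the coordinate origin, ``y`` increases with
native-dimension (first-dimension) migration downward and ``x`` increases
with denatured-dimension (second-dimension) migration rightward.

The mobility law is semi-log with a limiting mobility: migration distance is
affine in ``log(length)`` between a resolving floor ``L_min`` and a
saturation size ``L_sat``; molecules at or above ``L_sat`` stay at the
limiting distance near the well.  Because both axes use the same law, the
locus of double-stranded fragments co-migrating with the marker (the "arc")
is a straight diagonal segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np

from .molecules import (
    BEND_KINDS,
    INTERSTRAND,
    CrosslinkNetwork,
    DuplexMolecule,
    Lesion,
    Molecule,
    MoleculePopulation,
    StrandSegment,
    apoptotic_fragmentation,
    denature,
    induce_crosslink_damage,
    induce_dsbs,
    induce_nicks,
    mbo1_digest,
)

__all__ = [
    "MobilityModel",
    "LadderSpec",
    "MigrationSpot",
    "GelImage",
    "d1_migration",
    "d2_migration",
    "project_population",
    "ladder_spots",
    "render_gel",
    "simulate_experiment",
    "SCENARIOS",
    "SimulationResult",
]


@dataclass(frozen=True)
class MobilityModel:
    """Phenomenological migration-distance parameters (pixels)."""

    d1_max: float = 950.0
    d1_lim: float = 60.0
    d2_max: float = 950.0
    d2_lim: float = 60.0
    L_min: int = 50
    L_sat: int = 20000
    ss_d1_factor: float = 0.85
    bend_kappa: float = 0.15
    psf_sigma_px: float = 4.0
    noise_sd: float = 12.0
    background_level: float = 500.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if not self.d1_lim < self.d1_max:
            raise ValueError("need d1_lim < d1_max")
        if not self.d2_lim < self.d2_max:
            raise ValueError("need d2_lim < d2_max")
        if not self.L_min < self.L_sat:
            raise ValueError("need L_min < L_sat")
        if not 0 < self.ss_d1_factor <= 1:
            raise ValueError("ss_d1_factor must be in (0, 1]")
        if self.bend_kappa < 0:
            raise ValueError("bend_kappa must be >= 0")


DEFAULT_LADDER_SIZES = (100, 200, 300, 400, 500, 600, 700, 800, 900, 1000, 1200, 1500, 2000, 3000)


@dataclass(frozen=True)
class LadderSpec:
    """Double-stranded size marker (Cy5 channel)."""

    band_sizes: tuple[int, ...] = DEFAULT_LADDER_SIZES
    band_masses: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.band_sizes)
        if list(sizes) != sorted(set(sizes)):
            raise ValueError("ladder sizes must be strictly increasing")
        object.__setattr__(self, "band_sizes", sizes)
        if self.band_masses is None:
            object.__setattr__(self, "band_masses", tuple(3.0e4 for _ in sizes))
        elif len(self.band_masses) != len(sizes):
            raise ValueError("band_masses must match band_sizes")
        elif any(m <= 0 for m in self.band_masses):
            raise ValueError("band masses must be positive")


SOURCE_CLASSES = ("unmigrated", "ds_arc", "behind", "front_bent", "front_ss", "ssb_streak", "ladder")


@dataclass
class MigrationSpot:
    x_px: float
    y_px: float
    mass: float
    channel: str = "stain"  # 'stain' | 'cy5'
    source_class: str = "ds_arc"
    source: Optional[Molecule] = None

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError("spot mass must be >= 0")
        if self.source_class not in SOURCE_CLASSES:
            raise ValueError(f"unknown source_class {self.source_class!r}")


@dataclass
class GelImage:
    """Two-channel gel raster; intensities are non-negative floats."""

    stain_channel: np.ndarray
    cy5_channel: np.ndarray
    well_origin: tuple[float, float] = (0.0, 0.0)
    px_per_mm: float = 10.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stain_channel.shape != self.cy5_channel.shape:
            raise ValueError("channels must have the same shape")
        if not (np.isfinite(self.stain_channel).all() and np.isfinite(self.cy5_channel).all()):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.stain_channel.shape


# ---------------------------------------------------------------------------
# migration laws
# ---------------------------------------------------------------------------


def _log_law(length: float, lim: float, dmax: float, L_min: int, L_sat: int) -> float:
    frac = math.log(L_sat / length) / math.log(L_sat / L_min)
    return lim + (dmax - lim) * min(1.0, max(0.0, frac))


def d1_migration(entry: Molecule, model: MobilityModel) -> float:
    """Native-dimension migration distance (pixels downward from the well)."""
    if isinstance(entry, CrosslinkNetwork):
        length = entry.parent_duplex_length
        bends = entry.parent_bend_count
        ss = entry.member_segments[0].is_ss_in_d1
    elif isinstance(entry, StrandSegment):
        if entry.is_ss_in_d1:
            length, bends, ss = entry.length, 0, True
        else:
            length, bends, ss = entry.parent_duplex_length, entry.parent_bend_count, False
    elif isinstance(entry, DuplexMolecule):
        # crosslinked duplexes renature quickly and keep duplex mobility
        length, bends = entry.length, entry.bend_count
        ss = entry.denatured and entry.interstrand_count == 0
    else:
        raise TypeError(f"cannot migrate {type(entry).__name__}")
    if length <= 0:
        raise ValueError("length must be positive")
    y = _log_law(length, model.d1_lim, model.d1_max, model.L_min, model.L_sat)
    if ss:
        y *= model.ss_d1_factor
    if bends:
        y /= 1.0 + model.bend_kappa * bends
    return y


def d2_migration(entry: Union[StrandSegment, CrosslinkNetwork], model: MobilityModel) -> float:
    """Denatured-dimension migration distance: length-only, no modifiers."""
    if isinstance(entry, CrosslinkNetwork):
        length = entry.effective_length
    elif isinstance(entry, StrandSegment):
        length = entry.length
    else:
        raise TypeError("second-dimension migration applies to denatured species only")
    if length <= 0:
        raise ValueError("effective length must be positive")
    return _log_law(length, model.d2_lim, model.d2_max, model.L_min, model.L_sat)


def _classify(entry: Molecule, model: MobilityModel) -> str:
    if isinstance(entry, CrosslinkNetwork):
        return "behind"
    assert isinstance(entry, StrandSegment)
    if entry.origin_label == "ladder":
        return "ladder"
    if entry.parent_duplex_length >= model.L_sat and not entry.is_ss_in_d1:
        return "unmigrated" if entry.length == entry.parent_duplex_length else "ssb_streak"
    if entry.length >= model.L_sat:
        return "unmigrated"
    if entry.is_ss_in_d1:
        return "front_ss"
    if entry.parent_bend_count > 0:
        return "front_bent"
    return "ds_arc"


def project_population(
    pop: MoleculePopulation, model: MobilityModel, digested: bool = True
) -> list[MigrationSpot]:
    """Map a population to gel coordinates.

    Duplexes still present are denatured in-gel first (idempotent).  Each
    denatured species lands at ``x`` given by its own effective length and
    ``y`` given by its parent's native-phase migration.  Total spot mass
    equals total population mass exactly.
    """
    if len(pop) == 0:
        raise ValueError("empty population")
    pop = denature(pop, context="between_dimensions")
    spots = []
    for entry in pop:
        mol = entry.molecule
        cls = _classify(mol, model)
        x = d2_migration(mol, model)
        y = d1_migration(mol, model)
        channel = "cy5" if cls == "ladder" else "stain"
        spots.append(MigrationSpot(x, y, entry.mass_weight, channel, cls, source=mol))
    return spots


def ladder_spots(ladder: LadderSpec, model: MobilityModel) -> list[MigrationSpot]:
    """Cy5 marker bands: duplexes of each nominal size, run through both
    dimensions (native as duplex, denatured by own strand length)."""
    out = []
    for size, mass in zip(ladder.band_sizes, ladder.band_masses):
        seg = StrandSegment(length=size, parent_duplex_length=size, origin_label="ladder")
        out.append(
            MigrationSpot(
                d2_migration(seg, model),
                d1_migration(seg, model),
                mass,
                channel="cy5",
                source_class="ladder",
                source=seg,
            )
        )
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _stamp(channel: np.ndarray, x: float, y: float, mass: float, sigma: float) -> None:
    h, w = channel.shape
    r = max(1, int(math.ceil(4.0 * sigma)))
    cx, cy = int(round(x)), int(round(y))
    x0, x1 = max(0, cx - r), min(w, cx + r + 1)
    y0, y1 = max(0, cy - r), min(h, cy + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x
    ys = np.arange(y0, y1) - y
    gx = np.exp(-0.5 * (xs / sigma) ** 2)
    gy = np.exp(-0.5 * (ys / sigma) ** 2)
    kern = np.outer(gy, gx)
    kern *= mass / (2.0 * math.pi * sigma * sigma)
    channel[y0:y1, x0:x1] += kern


def render_gel(
    spots: Sequence[MigrationSpot],
    ladder: Optional[LadderSpec],
    model: MobilityModel,
    image_shape: tuple[int, int] = (1024, 1024),
    seed: int = 0,
) -> GelImage:
    """Rasterize spots as isotropic Gaussians plus marker, background and
    seeded Gaussian noise (clipped at zero).

    Spots are clipped to the raster; integrated signal above background is
    proportional to total mass within the PSF truncation tolerance (<1%).
    """
    h, w = image_shape
    if h <= 0 or w <= 0:
        raise ValueError("image shape must be positive")
    stain = np.zeros((h, w), dtype=np.float64)
    cy5 = np.zeros((h, w), dtype=np.float64)
    all_spots = list(spots)
    if ladder is not None:
        all_spots += ladder_spots(ladder, model)
    for s in all_spots:
        target = cy5 if s.channel == "cy5" else stain
        _stamp(target, s.x_px, s.y_px, s.mass * model.gain, model.psf_sigma_px)
    rng = np.random.default_rng(seed)
    stain += model.background_level + rng.normal(0.0, model.noise_sd, size=(h, w))
    cy5 += model.background_level + rng.normal(0.0, model.noise_sd, size=(h, w))
    np.clip(stain, 0.0, None, out=stain)
    np.clip(cy5, 0.0, None, out=cy5)
    return GelImage(
        stain_channel=stain,
        cy5_channel=cy5,
        well_origin=(0.0, 0.0),
        metadata={"model": asdict(model), "seed": seed, "n_spots": len(all_spots)},
    )


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

SCENARIOS = (
    "clean",
    "cisplatin",
    "nicking",
    "dsb",
    "apoptosis",
    "parp",
    "heat_denatured",
    "interstrand_fraction",
)


@dataclass
class SimulationResult:
    undigested: GelImage
    digested: GelImage
    truth: dict
    undigested_spots: list[MigrationSpot]
    digested_spots: list[MigrationSpot]


def _genomic_population(n_molecules: int, length: int) -> MoleculePopulation:
    pop = MoleculePopulation(seed_provenance="synthetic-genomic")
    for _ in range(n_molecules):
        pop.add(DuplexMolecule(length=length, origin_label="genomic"), mass_weight=float(20 * length))
    return pop


def _class_fractions(spots: Sequence[MigrationSpot]) -> dict[str, float]:
    total = sum(s.mass for s in spots if s.channel == "stain")
    out = {c: 0.0 for c in SOURCE_CLASSES if c != "ladder"}
    for s in spots:
        if s.channel == "stain":
            out[s.source_class] += s.mass / total
    return out


def _fragment_population(
    n_fragments: int, lo: int, hi: int, seed: int, interstrand_fraction: float = 0.0
) -> MoleculePopulation:
    """Equal-mass duplex fragments with log-uniform lengths in [lo, hi]; a
    deterministic leading share carries one interstrand crosslink each."""
    rng = np.random.default_rng(seed)
    lengths = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_fragments)).astype(int)
    n_xl = int(round(interstrand_fraction * n_fragments))
    pop = MoleculePopulation(seed_provenance=f"fragments(seed={seed})")
    for i, L in enumerate(lengths):
        lesions = ()
        if i < n_xl:
            lesions = (Lesion(INTERSTRAND, int(L) // 2, "both"),)
        pop.add(
            DuplexMolecule(length=int(L), lesions=lesions, origin_label="fragment"),
            float(20 * L),
        )
    return pop


def simulate_experiment(
    scenario: str,
    params: Optional[dict] = None,
    model: Optional[MobilityModel] = None,
    ladder: Optional[LadderSpec] = None,
    image_shape: tuple[int, int] = (1024, 1024),
    seed: int = 0,
) -> SimulationResult:
    """Run a full in-silico experiment: damage, paired digestion, in-gel
    denaturation, projection and rendering of both gels of the pair.

    Returns both rendered gels plus ground-truth mass fractions per source
    class for each member.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    p = dict(params or {})
    model = model or MobilityModel()
    ladder = ladder or LadderSpec()
    ss = np.random.SeedSequence(seed)
    s_damage, s_digest, s_noise_u, s_noise_d = (int(c.generate_state(1)[0]) for c in ss.spawn(4))

    n_mol = int(p.get("n_molecules", 20))
    length = int(p.get("molecule_length", 50000))

    if scenario == "apoptosis":
        repeat = int(p.get("repeat_length", 180))
        n_repeats = int(p.get("n_repeats", 220))
        substrate = MoleculePopulation(seed_provenance="chromatin")
        for _ in range(n_mol):
            substrate.add(
                DuplexMolecule(length=repeat * n_repeats, origin_label="chromatin"),
                float(20 * repeat * n_repeats),
            )
        # a share of the chromatin escapes linker cleavage but still picks up
        # single-strand breaks, feeding the unmigrated blob and the streak
        f_nicked = float(p.get("fraction_nicked_only", 0.25))
        cleaved = MoleculePopulation(seed_provenance="chromatin-cleaved")
        nicked_only = MoleculePopulation(seed_provenance="chromatin-nicked")
        for e in substrate:
            cleaved.add(e.molecule, e.mass_weight * (1.0 - f_nicked))
            if f_nicked > 0:
                nicked_only.add(e.molecule, e.mass_weight * f_nicked)
        damaged = apoptotic_fragmentation(
            cleaved,
            repeat_length=repeat,
            core_length=int(p.get("core_length", 147)),
            p_linker_cleave=float(p.get("p_linker_cleave", 0.5)),
            ssb_in_linker_rate=float(p.get("ssb_in_linker_rate", 0.0)),
            seed=s_damage,
        )
        if f_nicked > 0:
            damaged.entries.extend(
                induce_nicks(
                    nicked_only,
                    rate_per_nt=float(p.get("intact_nick_rate", 5e-4)),
                    strand_mode="both",
                    seed=s_damage + 1,
                ).entries
            )
    elif scenario == "interstrand_fraction":
        damaged = _fragment_population(
            n_fragments=int(p.get("n_fragments", 600)),
            lo=int(p.get("min_length", 150)),
            hi=int(p.get("max_length", 800)),
            seed=s_damage,
            interstrand_fraction=float(p.get("fraction", 0.0)),
        )
    else:
        base = _genomic_population(n_mol, length)
        if scenario == "clean":
            damaged = base
        elif scenario in ("cisplatin", "heat_denatured"):
            damaged = induce_crosslink_damage(
                base,
                dose=float(p.get("dose", 4.0)),
                lesion_rate_per_nt_per_dose=float(p.get("lesion_rate", 2e-3)),
                mix=p.get("mix"),
                denaturation_density_threshold=float(p.get("denaturation_threshold", 1 / 200)),
                seed=s_damage,
            )
        elif scenario == "nicking":
            damaged = induce_nicks(
                base, rate_per_nt=float(p.get("nick_rate", 2e-3)), strand_mode="both", seed=s_damage
            )
        elif scenario == "dsb":
            damaged = induce_dsbs(base, rate_per_nt=float(p.get("dsb_rate", 2e-3)), seed=s_damage)
        elif scenario == "parp":
            damaged = induce_nicks(
                base, rate_per_nt=float(p.get("nick_rate", 1e-3)), strand_mode="both", seed=s_damage
            )
            damaged = induce_dsbs(
                damaged, rate_per_nt=float(p.get("dsb_rate", 5e-4)), seed=s_damage + 1
            )

    undig_pop = damaged
    if scenario == "interstrand_fraction":
        # the fragment population already stands for the digest product
        dig_pop = damaged
    else:
        dig_pop = mbo1_digest(damaged, length_mode=True, seed=s_digest)
    if scenario == "heat_denatured" and p.get("heat", True):
        undig_pop = denature(undig_pop, context="pre_load")
        dig_pop = denature(dig_pop, context="pre_load")

    undig_spots = project_population(undig_pop, model, digested=False)
    dig_spots = project_population(dig_pop, model, digested=True)
    gel_u = render_gel(undig_spots, ladder, model, image_shape, seed=s_noise_u)
    gel_d = render_gel(dig_spots, ladder, model, image_shape, seed=s_noise_d)
    for gel, which in ((gel_u, "undigested"), (gel_d, "digested")):
        gel.metadata.update({"scenario": scenario, "params": p, "member": which, "seed": seed})
    truth = {
        "scenario": scenario,
        "params": p,
        "seed": seed,
        "undigested": _class_fractions(undig_spots),
        "digested": _class_fractions(dig_spots),
    }
    return SimulationResult(gel_u, gel_d, truth, undig_spots, dig_spots)
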