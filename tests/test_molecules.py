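import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sde2d.molecules import (
    INTERSTRAND,
    INTRASTRAND,
    MONOADDUCT,
    CrosslinkNetwork,
    DuplexMolecule,
    Lesion,
    MoleculePopulation,
    StrandSegment,
    _split_duplex,
    apoptotic_fragmentation,
    denature,
    induce_crosslink_damage,
    induce_dsbs,
    induce_nicks,
    is_amplifiable,
    mbo1_digest,
    read_jsonl,
    write_jsonl,
)


def pop_of(*molecules, mass=None):
    pop = MoleculePopulation()
    for i, m in enumerate(molecules):
        pop.add(m, mass[i] if mass else float(m.total_nucleotides))
    return pop


def scan_site_oracle(seq, site="GATC"):
    """Independent linear scan: fragment lengths from cut-at-site-start."""
    cuts = [i for i in range(len(seq) - len(site) + 1) if seq[i : i + len(site)] == site and i > 0]
    bounds = [0, *cuts, len(seq)]
    return [b - a for a, b in zip(bounds[:-1], bounds[1:])]


class TestTypes:
    def test_interstrand_requires_both(self):
        with pytest.raises(ValueError):
            Lesion(INTERSTRAND, 5, "top")
        with pytest.raises(ValueError):
            Lesion(MONOADDUCT, 5, "both")

    def test_nick_bounds(self):
        with pytest.raises(ValueError):
            DuplexMolecule(length=10, nicks_top=(0,))
        with pytest.raises(ValueError):
            DuplexMolecule(length=10, nicks_top=(10,))
        DuplexMolecule(length=10, nicks_top=(1, 9))

    def test_lesion_bounds(self):
        with pytest.raises(ValueError):
            DuplexMolecule(length=10, lesions=(Lesion(MONOADDUCT, 10, "top"),))

    def test_segment_not_longer_than_parent(self):
        with pytest.raises(ValueError):
            StrandSegment(length=11, parent_duplex_length=10)

    def test_network_needs_two_members(self):
        s = StrandSegment(length=5, parent_duplex_length=5)
        with pytest.raises(ValueError):
            CrosslinkNetwork((s,))
        net = CrosslinkNetwork((s, s))
        assert net.effective_length == 10


class TestMbo1Digest:
    def test_no_site_single_fragment(self):
        pop = pop_of(DuplexMolecule(length=40, sequence="ACGT" * 10))
        out = mbo1_digest(pop)
        assert len(out) == 1
        assert out.entries[0].molecule.length == 40

    def test_two_sites_oracle(self):
        seq = "A" * 10 + "GATC" + "A" * 16 + "GATC" + "A" * 16
        assert len(seq) == 50
        expected = scan_site_oracle(seq)
        assert expected == [10, 20, 20]
        out = mbo1_digest(pop_of(DuplexMolecule(length=50, sequence=seq)))
        assert [e.molecule.length for e in out] == expected

    def test_cuts_single_strands(self):
        seg = StrandSegment(length=30, parent_duplex_length=30, sequence="A" * 13 + "GATC" + "A" * 13)
        out = mbo1_digest(pop_of(seg))
        assert len(out) == 2
        assert sorted(e.molecule.length for e in out) == [13, 17]

    def test_lesion_blocks_cut(self):
        seq = "A" * 10 + "GATC" + "A" * 16
        mol = DuplexMolecule(length=30, sequence=seq, lesions=(Lesion(MONOADDUCT, 12, "top"),))
        out = mbo1_digest(pop_of(mol), lesion_block_window=4)
        assert len(out) == 1
        far = DuplexMolecule(length=30, sequence=seq, lesions=(Lesion(MONOADDUCT, 25, "top"),))
        assert len(mbo1_digest(pop_of(far), lesion_block_window=4)) == 2

    def test_invalid_site(self):
        with pytest.raises(ValueError):
            mbo1_digest(pop_of(DuplexMolecule(length=4, sequence="ACGT")), site="GAXC")

    def test_sequence_required_without_length_mode(self):
        with pytest.raises(ValueError):
            mbo1_digest(pop_of(DuplexMolecule(length=100)))

    def test_length_mode_mean_fragment(self):
        pop = pop_of(DuplexMolecule(length=200000))
        out = mbo1_digest(pop, length_mode=True, seed=0)
        mean_len = np.mean([e.molecule.length for e in out])
        # geometric with mean 256 for a 4-cutter
        assert 200 < mean_len < 320

    def test_fragments_inherit_and_rehome(self):
        seq = "A" * 10 + "GATC" + "A" * 16
        mol = DuplexMolecule(
            length=30, sequence=seq, nicks_top=(20,), lesions=(Lesion(MONOADDUCT, 25, "top"),)
        )
        out = mbo1_digest(pop_of(mol))
        frag2 = out.entries[1].molecule
        assert frag2.length == 20
        assert frag2.nicks_top == (10,)
        assert frag2.lesions[0].position == 15


class TestInduceNicks:
    def test_zero_rate_identity(self):
        pop = pop_of(DuplexMolecule(length=1000))
        out = induce_nicks(pop, rate_per_nt=0.0, seed=1)
        assert out.entries[0].molecule == pop.entries[0].molecule

    def test_poisson_mean_monte_carlo(self):
        rate, L, n = 0.01, 1000, 300
        counts = []
        for seed in range(n):
            out = induce_nicks(pop_of(DuplexMolecule(length=L)), rate_per_nt=rate, seed=seed)
            m = out.entries[0].molecule
            counts.append(len(m.nicks_top) + len(m.nicks_bottom))
        se = np.sqrt(rate * L / n)
        assert abs(np.mean(counts) - rate * L) < 3 * se

    def test_recognition_mode_top_only(self):
        seq = "T" * 10 + "GAGTC" + "T" * 15
        out = induce_nicks(
            pop_of(DuplexMolecule(length=30, sequence=seq)),
            recognition="GAGTC",
            strand_mode="top_only",
            seed=0,
        )
        m = out.entries[0].molecule
        assert m.nicks_top == (15,)  # nick placed 3' of the recognition site
        assert m.nicks_bottom == ()

    def test_negative_rate(self):
        with pytest.raises(ValueError):
            induce_nicks(pop_of(DuplexMolecule(length=10)), rate_per_nt=-1.0)


class TestInduceDsbs:
    def test_zero_rate_identity(self):
        pop = pop_of(DuplexMolecule(length=500))
        out = induce_dsbs(pop, 0.0, seed=2)
        assert len(out) == 1 and out.entries[0].molecule.length == 500

    def test_single_cut_arithmetic(self):
        frags = _split_duplex(DuplexMolecule(length=1000), [100])
        assert [f.length for f in frags] == [100, 900]

    def test_fragment_count_distribution(self):
        rate, L, n = 0.005, 2000, 300
        counts = [len(induce_dsbs(pop_of(DuplexMolecule(length=L)), rate, seed=s)) for s in range(n)]
        expected = 1 + rate * L  # 1 + Poisson mean
        se = np.sqrt(rate * L / n)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_negative_rate(self):
        with pytest.raises(ValueError):
            induce_dsbs(pop_of(DuplexMolecule(length=10)), -0.1)


class TestCrosslinkDamage:
    def test_zero_dose_no_lesions(self):
        out = induce_crosslink_damage(pop_of(DuplexMolecule(length=1000)), dose=0.0, seed=0)
        assert out.entries[0].molecule.lesions == ()

    def test_mean_lesion_count(self):
        dose, rate, L, n = 2.0, 0.002, 1000, 300
        counts = [
            len(
                induce_crosslink_damage(
                    pop_of(DuplexMolecule(length=L)), dose=dose, lesion_rate_per_nt_per_dose=rate, seed=s
                ).entries[0].molecule.lesions
            )
            for s in range(n)
        ]
        mean = dose * rate * L
        se = np.sqrt(mean / n)
        assert abs(np.mean(counts) - mean) < 3 * se

    def test_dose_increases_interstrand(self):
        def mean_xl(dose):
            tot = 0
            for s in range(40):
                out = induce_crosslink_damage(
                    pop_of(DuplexMolecule(length=5000)), dose=dose, seed=s
                )
                tot += out.entries[0].molecule.interstrand_count
            return tot / 40

        assert mean_xl(1.0) < mean_xl(4.0) < mean_xl(8.0)

    def test_bad_mix(self):
        with pytest.raises(ValueError):
            induce_crosslink_damage(
                pop_of(DuplexMolecule(length=10)), dose=1.0, mix={INTERSTRAND: 0.5, INTRASTRAND: 0.4}
            )

    def test_density_threshold_flags_denatured(self):
        out = induce_crosslink_damage(
            pop_of(DuplexMolecule(length=2000)),
            dose=10.0,
            lesion_rate_per_nt_per_dose=0.005,
            mix={INTERSTRAND: 0.0, INTRASTRAND: 0.8, MONOADDUCT: 0.2},
            denaturation_density_threshold=1 / 200,
            seed=0,
        )
        assert out.entries[0].molecule.denatured


class TestApoptoticFragmentation:
    def test_full_cleavage_mononucleosomes(self):
        pop = pop_of(DuplexMolecule(length=180 * 100))
        out = apoptotic_fragmentation(pop, p_linker_cleave=1.0, seed=0)
        assert all(e.molecule.length == 180 for e in out)

    def test_identity_at_zero(self):
        pop = pop_of(DuplexMolecule(length=180 * 10))
        out = apoptotic_fragmentation(pop, p_linker_cleave=0.0, ssb_in_linker_rate=0.0, seed=0)
        assert len(out) == 1 and out.entries[0].molecule.length == 1800

    def test_half_cleavage_geometric_mean(self):
        lengths = []
        for s in range(200):
            out = apoptotic_fragmentation(
                pop_of(DuplexMolecule(length=180 * 100)), p_linker_cleave=0.5, seed=s
            )
            lengths += [e.molecule.length for e in out]
        # geometric in repeat units, mean ~2 repeats
        assert abs(np.mean(lengths) / 180 - 2.0) < 0.2

    def test_lengths_are_repeat_multiples(self):
        out = apoptotic_fragmentation(
            pop_of(DuplexMolecule(length=180 * 50)), p_linker_cleave=0.3, seed=7
        )
        assert all(e.molecule.length % 180 == 0 for e in out)

    def test_bad_probability(self):
        with pytest.raises(ValueError):
            apoptotic_fragmentation(pop_of(DuplexMolecule(length=360)), p_linker_cleave=1.5)


class TestDenature:
    def test_intact_duplex_two_strands(self):
        out = denature(pop_of(DuplexMolecule(length=500)))
        assert len(out) == 2
        assert all(e.molecule.length == 500 for e in out)

    def test_crosslinked_duplex_network(self):
        mol = DuplexMolecule(length=500, lesions=(Lesion(INTERSTRAND, 250, "both"),))
        out = denature(pop_of(mol))
        assert len(out) == 1
        net = out.entries[0].molecule
        assert isinstance(net, CrosslinkNetwork)
        assert net.effective_length == 1000

    def test_nick_splitting_oracle(self):
        mol = DuplexMolecule(length=500, nicks_top=(200,))
        out = denature(pop_of(mol))
        assert sorted(e.molecule.length for e in out) == [200, 300, 500]

    def test_idempotent(self):
        mol = DuplexMolecule(length=500, nicks_top=(100,), lesions=(Lesion(INTERSTRAND, 300, "both"),))
        once = denature(pop_of(mol))
        twice = denature(once)
        assert [type(e.molecule).__name__ for e in once] == [
            type(e.molecule).__name__ for e in twice
        ]
        assert [e.molecule.total_nucleotides for e in once] == [
            e.molecule.total_nucleotides for e in twice
        ]

    def test_pre_load_free_duplex_single_stranded(self):
        out = denature(pop_of(DuplexMolecule(length=400)), context="pre_load")
        assert all(e.molecule.is_ss_in_d1 for e in out)

    def test_pre_load_network_renatures(self):
        mol = DuplexMolecule(length=400, lesions=(Lesion(INTERSTRAND, 100, "both"),))
        out = denature(pop_of(mol), context="pre_load")
        net = out.entries[0].molecule
        assert isinstance(net, CrosslinkNetwork)
        assert not any(s.is_ss_in_d1 for s in net.member_segments)

    def test_sequence_revcomp(self):
        mol = DuplexMolecule(length=4, sequence="ACGT")
        out = denature(pop_of(mol))
        seqs = sorted(e.molecule.sequence for e in out)
        assert seqs == ["ACGT", "ACGT"]  # ACGT is its own reverse complement

    def test_nick_between_crosslinks_three_member_network(self):
        mol = DuplexMolecule(
            length=600,
            nicks_top=(300,),
            lesions=(Lesion(INTERSTRAND, 100, "both"), Lesion(INTERSTRAND, 500, "both")),
        )
        out = denature(pop_of(mol))
        assert len(out) == 1
        assert len(out.entries[0].molecule.member_segments) == 3


class TestAmplifiability:
    def test_intact_duplex(self):
        assert is_amplifiable(DuplexMolecule(length=100))

    def test_crosslinked_duplex(self):
        assert not is_amplifiable(
            DuplexMolecule(length=100, lesions=(Lesion(INTERSTRAND, 50, "both"),))
        )

    def test_nicked_duplex_still_amplifiable(self):
        assert is_amplifiable(DuplexMolecule(length=100, nicks_top=(10, 20, 30)))

    def test_network_never_amplifiable(self):
        s = StrandSegment(length=5, parent_duplex_length=5)
        assert not is_amplifiable(CrosslinkNetwork((s, s)))

    def test_partition_invariant(self):
        rng = np.random.default_rng(5)
        pop = MoleculePopulation()
        for i in range(50):
            lesions = (Lesion(INTERSTRAND, 10, "both"),) if rng.random() < 0.4 else ()
            pop.add(DuplexMolecule(length=100, lesions=lesions), float(rng.integers(1, 10)))
        non_amp = sum(e.mass_weight for e in pop if not is_amplifiable(e.molecule))
        xl_mass = sum(e.mass_weight for e in pop if e.molecule.interstrand_count > 0)
        assert non_amp == xl_mass


@st.composite
def random_population(draw):
    pop = MoleculePopulation()
    n = draw(st.integers(1, 5))
    for _ in range(n):
        L = draw(st.integers(10, 2000))
        pop.add(DuplexMolecule(length=L), float(2 * L))
    return pop


class TestConservationProperties:
    @settings(max_examples=25, deadline=None)
    @given(random_population(), st.integers(0, 2**31 - 1))
    def test_nucleotide_conservation(self, pop, seed):
        before = pop.total_nucleotides
        for op in (
            lambda p: mbo1_digest(p, length_mode=True, seed=seed),
            lambda p: induce_nicks(p, rate_per_nt=0.01, seed=seed),
            lambda p: induce_dsbs(p, 0.005, seed=seed),
            lambda p: induce_crosslink_damage(p, dose=2.0, seed=seed),
            lambda p: apoptotic_fragmentation(p, p_linker_cleave=0.5, seed=seed),
            denature,
        ):
            assert op(pop).total_nucleotides == before

    @settings(max_examples=25, deadline=None)
    @given(random_population(), st.integers(0, 2**31 - 1))
    def test_mass_conservation(self, pop, seed):
        before = pop.total_mass
        out = denature(induce_nicks(pop, rate_per_nt=0.01, seed=seed))
        assert out.total_mass == pytest.approx(before, rel=1e-12)

    def test_seed_determinism(self):
        pop = pop_of(DuplexMolecule(length=5000))
        a = induce_crosslink_damage(pop, dose=3.0, seed=42)
        b = induce_crosslink_damage(pop, dose=3.0, seed=42)
        assert a.entries[0].molecule == b.entries[0].molecule
        c = induce_nicks(pop, rate_per_nt=0.01, seed=9)
        d = induce_nicks(pop, rate_per_nt=0.01, seed=9)
        assert c.entries[0].molecule == d.entries[0].molecule


class TestIO:
    def test_jsonl_round_trip(self, tmp_path):
        mol = DuplexMolecule(
            length=100,
            nicks_top=(10,),
            lesions=(Lesion(INTERSTRAND, 50, "both"),),
            origin_label="x",
        )
        net = denature(pop_of(mol)).entries[0].molecule
        pop = MoleculePopulation()
        pop.add(mol, 2.0)
        pop.add(StrandSegment(length=30, parent_duplex_length=60), 1.0)
        pop.add(net, 0.5)
        path = tmp_path / "pop.jsonl"
        write_jsonl(pop, path)
        back = read_jsonl(path)
        assert len(back) == 3
        assert back.entries[0].molecule == mol
        assert back.total_mass == pop.total_mass

    def test_fasta_reader(self, tmp_path):
        from sde2d.molecules import read_fasta_population

        fa = tmp_path / "in.fa"
        fa.write_text(">a\nACGTACGT\n>b\nGGGGATCC\n")
        pop = read_fasta_population(fa)
        assert [e.molecule.length for e in pop] == [8, 8]
        assert pop.entries[0].molecule.sequence == "ACGTACGT"
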