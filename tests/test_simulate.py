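"""Synthetic-data generator: references, molecules, conversion, reads, digestion."""

import io

import numpy as np
import pytest

import methylguide as mg
from methylguide.scanner import Cytosine, SequenceRecord, enumerate_target_sites, find_cpgs
from methylguide.simulate import (
    FSPI_SITE,
    MethylationSpec,
    MoleculeState,
    bisulfite_convert,
    build_reference,
    digest_fsp1,
    parse_read_name,
    sample_molecules,
    sample_reads,
    write_fastq,
)


class TestBuildReference:
    def test_planted_target_recovered_by_scanner(self):
        bundle = build_reference(10, [12], "linear", seed=3)
        planted = bundle.targets[0]
        sites = enumerate_target_sites(bundle.record, 12, 12)
        hits = [s for s in sites if s.pam.pam_start == planted.pam_start and s.pam.strand == "+"]
        assert len(hits) == 1
        assert hits[0].cpg.c_forward_pos == planted.cpg_forward_pos
        assert hits[0].cis_cytosine == planted.cis_cytosine
        assert hits[0].trans_cytosine == planted.trans_cytosine

    def test_minimal_reference_still_has_two_fspi_cpgs(self):
        bundle = build_reference(0, [], "linear", seed=1)
        assert len(bundle.fspi_sites) >= 2
        cpg_positions = {c.c_forward_pos for c in find_cpgs(bundle.record)}
        for s in bundle.fspi_sites:
            assert bundle.record.seq[s : s + 6] == FSPI_SITE
            assert s + 2 in cpg_positions  # TGCGCA carries its CpG at offsets 2-3

    def test_cpg_census_is_exactly_what_was_planted(self):
        bundle = build_reference(25, [12, 11], "circular", seed=5)
        found = {c.c_forward_pos for c in find_cpgs(bundle.record)}
        planted = set(bundle.offtarget_cpg_positions) | {t.cpg_forward_pos for t in bundle.targets}
        extra_fspi = {s + 2 for s in bundle.fspi_sites} - {t.fspi_start + 2 for t in bundle.targets}
        assert found == planted | extra_fspi

    def test_target_probabilities_and_labels(self):
        bundle = build_reference(40, [12], "circular", seed=7, target_p_cis=0.1, target_p_trans=0.344)
        t = bundle.targets[0]
        assert bundle.spec.probabilities[t.cis_cytosine] == 0.1
        assert bundle.spec.probabilities[t.trans_cytosine] == 0.344
        assert bundle.spec.target_labels == {t.cis_cytosine, t.trans_cytosine}
        off = [p for c, p in bundle.spec.probabilities.items() if c not in bundle.spec.target_labels]
        assert len(off) == 2 * (40 + 1)  # both strands of background + 1 non-target FspI CpG
        assert 0.0 < np.mean(off) < 0.02  # Beta background, mean 0.005

    def test_proximity_mode_inflates_near_target(self):
        flat = build_reference(100, [12], "circular", seed=9)
        prox = build_reference(100, [12], "circular", seed=9, proximity_window=200, proximity_factor=10.0)
        t = prox.targets[0].cpg_forward_pos
        near = [c for c in prox.offtarget_cpg_positions if abs(c - t) <= 200]
        assert near, "fixture must include background CpGs near the target"
        for c in near:
            cyt = Cytosine(c, "+")
            assert prox.spec.probabilities[cyt] >= flat.spec.probabilities[cyt]

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            build_reference(-1, [], "linear", seed=0)
        with pytest.raises(ValueError):
            build_reference(0, [1], "linear", seed=0)


class TestSampleMolecules:
    def test_degenerate_probabilities(self):
        rec = SequenceRecord("t", "AACGTT")
        spec = MethylationSpec(rec, {Cytosine(2, "+"): 0.0, Cytosine(3, "-"): 1.0})
        mols = sample_molecules(spec, 20, seed=0)
        assert all(not m.is_methylated(Cytosine(2, "+")) for m in mols)
        assert all(m.is_methylated(Cytosine(3, "-")) for m in mols)

    def test_empirical_fraction_within_binomial_error(self):
        rec = SequenceRecord("t", "AACGTT")
        p = 0.344
        spec = MethylationSpec(rec, {Cytosine(2, "+"): p})
        n = 10_000
        mols = sample_molecules(spec, n, seed=42)
        frac = sum(m.is_methylated(Cytosine(2, "+")) for m in mols) / n
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_seed_reproducibility(self):
        rec = SequenceRecord("t", "AACGTT")
        spec = MethylationSpec(rec, {Cytosine(2, "+"): 0.5})
        a = sample_molecules(spec, 50, seed=7)
        b = sample_molecules(spec, 50, seed=7)
        assert [m.methylated for m in a] == [m.methylated for m in b]

    def test_non_cytosine_site_rejected(self):
        rec = SequenceRecord("t", "AACGTT")
        with pytest.raises(ValueError):
            MethylationSpec(rec, {Cytosine(0, "+"): 0.5})


class TestBisulfiteConvert:
    def _spec(self, probabilities, efficiency=1.0):
        return MethylationSpec(SequenceRecord("t", "ACGT"), probabilities, conversion_efficiency=efficiency)

    def test_unmethylated_c_converts_to_t(self):
        spec = self._spec({})
        top, bottom = bisulfite_convert(MoleculeState(0, frozenset()), spec)
        assert top == "ATGT"
        assert bottom == "ATGT"  # revcomp(ACGT) = ACGT, same conversion

    def test_methylated_c_is_protected(self):
        spec = self._spec({Cytosine(1, "+"): 1.0})
        top, _ = bisulfite_convert(MoleculeState(0, frozenset({Cytosine(1, "+")})), spec)
        assert top == "ACGT"
        spec2 = self._spec({Cytosine(2, "-"): 1.0})
        _, bottom = bisulfite_convert(MoleculeState(0, frozenset({Cytosine(2, "-")})), spec2)
        assert bottom == "ACGT"

    def test_zero_efficiency_leaves_sequence_unchanged(self):
        spec = self._spec({}, efficiency=0.0)
        top, bottom = bisulfite_convert(MoleculeState(0, frozenset()), spec)
        assert top == "ACGT"
        assert bottom == "ACGT"

    def test_partial_efficiency_converts_expected_fraction(self):
        rec = SequenceRecord("t", "C" * 1000)
        spec = MethylationSpec(rec, {}, conversion_efficiency=0.8)
        rng = np.random.default_rng(0)
        top, _ = bisulfite_convert(MoleculeState(0, frozenset()), spec, rng=rng)
        frac_converted = top.count("T") / 1000
        assert abs(frac_converted - 0.8) < 3 * np.sqrt(0.8 * 0.2 / 1000)


@pytest.fixture(scope="module")
def bundle():
    return build_reference(20, [12], "circular", seed=11)


class TestSampleReads:
    def test_error_free_reads_are_exact_substrings(self, bundle):
        mols = sample_molecules(bundle.spec, 30, seed=1)
        reads = sample_reads(mols, bundle.spec, read_length=60, depth=30, error_rate=0.0, seed=2)
        L = len(bundle.record)
        converted = {m.molecule_id: bisulfite_convert(m, bundle.spec) for m in mols}
        for r in reads:
            mol_id, strand, fwd_start = parse_read_name(r.name)
            assert 0 <= fwd_start < L
            top, bottom = converted[mol_id]
            if strand == "+":
                expect = (top + top)[fwd_start : fwd_start + 60]
            else:
                s = (L - fwd_start - 60) % L
                expect = (bottom + bottom)[s : s + 60]
            assert r.seq == expect

    def test_mean_coverage_close_to_depth(self, bundle):
        mols = sample_molecules(bundle.spec, 50, seed=3)
        depth = 50
        reads = sample_reads(mols, bundle.spec, read_length=75, depth=depth, error_rate=0.0, seed=4)
        L = len(bundle.record)
        cov = np.zeros(L)
        for r in reads:
            _, strand, fwd_start = parse_read_name(r.name)
            idx = (np.arange(fwd_start, fwd_start + 75)) % L
            cov[idx] += 1
        assert abs(cov.mean() - depth) < 3 * np.sqrt(depth / L) + 1
        # circular record: no edge effects, every position covered
        assert cov.min() > 0

    def test_substitution_errors_at_requested_rate(self, bundle):
        mols = sample_molecules(bundle.spec, 10, seed=5)
        clean = sample_reads(mols, bundle.spec, read_length=75, depth=40, error_rate=0.0, seed=6)
        noisy = sample_reads(mols, bundle.spec, read_length=75, depth=40, error_rate=0.05, seed=6)
        diffs = sum(
            a != b for rc, rn in zip(clean, noisy) for a, b in zip(rc.seq, rn.seq)
        )
        total = sum(len(r.seq) for r in clean)
        assert abs(diffs / total - 0.05) < 3 * np.sqrt(0.05 * 0.95 / total)

    def test_read_length_validation(self, bundle):
        mols = sample_molecules(bundle.spec, 2, seed=0)
        with pytest.raises(ValueError):
            sample_reads(mols, bundle.spec, read_length=10 ** 6, depth=1, seed=0)


class TestSeedDeterminism:
    def test_identical_seeds_give_byte_identical_fastq(self):
        outputs = []
        for _ in range(2):
            bundle = build_reference(30, [12], "circular", seed=21)
            mols = sample_molecules(bundle.spec, 40, seed=22)
            reads = sample_reads(mols, bundle.spec, read_length=75, depth=25, error_rate=0.01, seed=23)
            buf = io.StringIO()
            write_fastq(reads, buf)
            outputs.append(buf.getvalue())
        assert outputs[0] == outputs[1]
        assert outputs[0].startswith("@mol")


class TestDigestFsp1:
    def _manual_spec(self, p_site1, p_site2, topology="linear"):
        # sites at 3 and 13; cut positions (blunt, after site offset 2) at 6 and 16
        seq = "AAA" + FSPI_SITE + "AAAA" + FSPI_SITE + "AAA"
        rec = SequenceRecord("t", seq, topology)
        probs = {
            Cytosine(5, "+"): p_site1,
            Cytosine(6, "-"): p_site1,
            Cytosine(15, "+"): p_site2,
            Cytosine(16, "-"): p_site2,
        }
        return MethylationSpec(rec, probs)

    def test_unmethylated_sites_cut_at_hand_computed_positions(self):
        spec = self._manual_spec(0.0, 0.0)
        mols = sample_molecules(spec, 5, seed=0)
        result = digest_fsp1(mols, spec)
        assert result.n_sites == 2
        assert result.protected_fraction == 0.0
        assert all(frags == (6, 10, 6) for frags in result.fragment_lengths)

    def test_one_protected_one_cut(self):
        spec = self._manual_spec(1.0, 0.0)
        mols = sample_molecules(spec, 5, seed=0)
        result = digest_fsp1(mols, spec)
        assert result.protected_fraction == 0.5
        assert all(frags == (16, 6) for frags in result.fragment_lengths)

    def test_fully_protected_single_fragment(self):
        spec = self._manual_spec(1.0, 1.0)
        mols = sample_molecules(spec, 5, seed=0)
        result = digest_fsp1(mols, spec)
        assert result.protected_fraction == 1.0
        assert all(frags == (22,) for frags in result.fragment_lengths)

    def test_fragment_lengths_conserve_molecule_length(self):
        bundle = build_reference(15, [12], "linear", seed=31, target_p_trans=0.7, offtarget_mean=0.2)
        mols = sample_molecules(bundle.spec, 40, seed=32)
        result = digest_fsp1(mols, bundle.spec)
        L = len(bundle.record)
        for frags in result.fragment_lengths:
            assert sum(frags) == L

    def test_circular_uncut_molecule_is_one_full_length_fragment(self):
        spec = self._manual_spec(1.0, 1.0, topology="circular")
        mols = sample_molecules(spec, 3, seed=0)
        result = digest_fsp1(mols, spec)
        assert all(frags == (22,) for frags in result.fragment_lengths)

    def test_circular_fragments_conserve_length(self):
        spec = self._manual_spec(0.5, 0.5, topology="circular")
        mols = sample_molecules(spec, 50, seed=1)
        result = digest_fsp1(mols, spec)
        for frags in result.fragment_lengths:
            assert sum(frags) == 22

    def test_protection_tracks_either_strand(self):
        # methylation on the reverse strand alone protects the site
        seq = "AAA" + FSPI_SITE + "AAA"
        rec = SequenceRecord("t", seq)
        spec = MethylationSpec(rec, {Cytosine(6, "-"): 1.0})
        mols = sample_molecules(spec, 3, seed=0)
        assert digest_fsp1(mols, spec).protected_fraction == 1.0
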