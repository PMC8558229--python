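"""Motif scanning against brute-force IUPAC expansion, clustering, correlation."""

import numpy as np
import pytest
from scipy import stats

from xbptargets.errors import (
    InvalidMotifError,
    InvalidSequenceError,
    UndefinedCorrelationError,
    XbpTargetsError,
)
from xbptargets.intervals import GenomicInterval, TSSAnnotation, promoter_window
from xbptargets.motifs import (
    IUPAC_CODES,
    GeneMotifReport,
    IUPACMotif,
    MotifHit,
    XBP1_CONSENSUS,
    correlate_counts_with_response,
    count_motifs_per_gene,
    find_homotypic_clusters,
    reverse_complement,
    scan_iupac,
)


def brute_force_scan(seq, pattern):
    """Position-by-position checker expanding every IUPAC code.

    The minus strand is handled by reverse-complementing the *window* and
    testing it against the forward pattern — an independent code path from
    the implementation's reverse-complemented-pattern regex.
    """
    k = len(pattern)
    hits = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if all(c in IUPAC_CODES[p] and c != "N" for c, p in zip(w, pattern)):
            hits.append((i, "+"))
        wrc = reverse_complement(w)
        if "N" not in w and all(c in IUPAC_CODES[p] for c, p in zip(wrc, pattern)):
            hits.append((i, "-"))
    return sorted(hits)


class TestScanIupac:
    def test_consensus_matches_concrete_instance(self):
        hits = scan_iupac("GACGTGGCATAA", XBP1_CONSENSUS)
        assert [(h.start, h.end, h.strand) for h in hits] == [(0, 12, "+")]
        assert hits[0].matched_sequence == "GACGTGGCATAA"

    def test_impossible_sequence_has_no_hits(self):
        assert scan_iupac("C" * 14, XBP1_CONSENSUS) == []

    def test_n_in_sequence_never_matches(self):
        assert scan_iupac("GACGTGGCATNA", XBP1_CONSENSUS) == []

    def test_invalid_nucleotide_reports_position(self):
        with pytest.raises(InvalidSequenceError, match="position 4"):
            scan_iupac("ACGTXACGT", "ACGT")

    def test_invalid_motif_code_rejected(self):
        with pytest.raises(InvalidMotifError):
            IUPACMotif("ACGTQ")

    def test_overlapping_hits_all_reported(self):
        # AAAA contains three overlapping AA matches
        hits = scan_iupac("AAAA", "AA", both_strands=False)
        assert [h.start for h in hits] == [0, 1, 2]

    def test_random_sequence_matches_brute_force_expansion(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=2_000))
        for pattern in (XBP1_CONSENSUS, "RYSWKM", "ACGT"):
            got = [(h.start, h.strand) for h in scan_iupac(seq, pattern)]
            assert sorted(got) == brute_force_scan(seq, pattern)

    def test_strand_symmetry_under_reverse_complement(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        fwd = scan_iupac(seq, XBP1_CONSENSUS)
        rev = scan_iupac(reverse_complement(seq), XBP1_CONSENSUS)
        assert len(fwd) == len(rev)
        mirrored = {
            (len(seq) - h.end, len(seq) - h.start, "+" if h.strand == "-" else "-")
            for h in fwd
        }
        assert {(h.start, h.end, h.strand) for h in rev} == mirrored


class TestCountMotifsPerGene:
    def _setup(self, seq, blocks, flank=30):
        chrom_length = len(seq)
        tss = TSSAnnotation("g1", "chrA", chrom_length // 2, "+")
        window = promoter_window(tss, flank, flank, chrom_length)
        open_chromatin = [GenomicInterval("chrA", s, e) for s, e in blocks]
        return {"chrA": seq}, [window], open_chromatin

    def test_only_fully_contained_accessible_hits_count(self):
        inst = "GACGTGGCATAA"
        seq = "T" * 10 + inst + "T" * 10 + inst + "T" * 10 + inst + "T" * 10
        # accessible: covers first instance fully, second partially, not third
        genome, windows, oc = self._setup(seq, [(5, 25), (30, 38)], flank=len(seq) // 2)
        reports = count_motifs_per_gene(genome, windows, oc, XBP1_CONSENSUS)
        assert reports[0].n_hits == 1
        assert reports[0].searched_bases == 28

    def test_no_open_chromatin_means_zero(self):
        seq = "GACGTGGCATAA" * 5
        genome, windows, _ = self._setup(seq, [])
        reports = count_motifs_per_gene(genome, windows, [], XBP1_CONSENSUS)
        assert reports[0].n_hits == 0 and reports[0].n_clusters == 0

    def test_missing_chromosome_names_gene(self):
        tss = TSSAnnotation("lost", "chrZ", 50, "+")
        window = promoter_window(tss, 10, 10, 100)
        with pytest.raises(XbpTargetsError, match="lost"):
            count_motifs_per_gene({"chrA": "A" * 100}, [window], [], "ACGT")


class TestHomotypicClusters:
    def _hits(self, starts):
        return [MotifHit("c", s, s + 12, "+", "A" * 12) for s in starts]

    def test_pair_within_gap_forms_one_cluster(self):
        n, spans = find_homotypic_clusters(self._hits([100, 300, 5_000]), max_gap=500)
        assert n == 1
        assert (spans[0].start, spans[0].end) == (100, 312)

    def test_single_hit_is_no_cluster(self):
        assert find_homotypic_clusters(self._hits([42]))[0] == 0

    def test_random_hits_match_run_length_oracle(self):
        rng = np.random.default_rng(5)
        starts = sorted(int(s) for s in rng.integers(0, 20_000, size=30))
        max_gap = 500
        # brute-force run-length scan over sorted starts
        runs, current = [], [starts[0]]
        for s in starts[1:]:
            if s - current[-1] <= max_gap:
                current.append(s)
            else:
                runs.append(current)
                current = [s]
        runs.append(current)
        expected = sum(1 for r in runs if len(r) >= 2)
        n, spans = find_homotypic_clusters(self._hits(starts), max_gap=max_gap)
        assert n == expected == len(spans)


class TestCorrelateCountsWithResponse:
    def _reports(self, counts):
        return [GeneMotifReport(f"g{i}", c, 0, 0) for i, c in enumerate(counts)]

    def test_counts_equal_to_log_responses_give_r_one(self):
        counts = [1, 2, 3, 4]
        responses = {f"g{i}": 2.0 ** c for i, c in enumerate(counts)}
        r, p = correlate_counts_with_response(self._reports(counts), responses)
        assert r == pytest.approx(1.0)

    def test_zero_variance_raises_instead_of_returning_number(self):
        responses = {f"g{i}": 2.0 for i in range(4)}
        with pytest.raises(UndefinedCorrelationError):
            correlate_counts_with_response(self._reports([3, 3, 3, 3]), responses)

    def test_matches_closed_form_covariance_computation(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 15, size=20)
        fold = np.exp(rng.normal(0, 1, size=20))
        responses = {f"g{i}": float(f) for i, f in enumerate(fold)}
        r, p = correlate_counts_with_response(self._reports(counts), responses)
        x = counts.astype(float)
        y = np.log2(fold)
        cov = ((x - x.mean()) * (y - y.mean())).sum()
        r_expected = cov / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        t = r_expected * np.sqrt(18 / (1 - r_expected**2))
        p_expected = 2 * stats.t.sf(abs(t), 18)
        assert r == pytest.approx(r_expected, abs=1e-12)
        assert p == pytest.approx(p_expected, rel=1e-9)

    def test_panel_counts_uncorrelated_with_induction(self, panel_fc, panel_motifs):
        genes = [g for g in panel_fc.index if g != "XBP1s"]
        reports = [GeneMotifReport(g, int(panel_motifs[g]), 0, 0) for g in genes]
        r, p = correlate_counts_with_response(
            reports, panel_fc.loc[genes, "induced_xbp1s"].to_dict()
        )
        assert abs(r) < 0.5 and p > 0.05
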