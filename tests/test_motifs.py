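"""IUPAC motif scanning, enrichment statistics and expression
integration."""

import re

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fungatac.genome import GeneAnnotation
from fungatac.motifs import (MotifModel, deg_flags, expand_consensus,
                             instances_to_targets, integrate_expression,
                             load_known_motifs, motif_enrichment,
                             reverse_complement_consensus, scan_motif)

PRTT = MotifModel.from_string("prtT", "CCGHCGG")


class TestConsensusParsing:
    def test_gap_notation_expansion(self):
        assert expand_consensus("CGG-N8-MGG") == "CGG" + "N" * 8 + "MGG"

    def test_slash_alternative(self):
        assert expand_consensus("CGGN8(C/A)GG") == "CGG" + "N" * 8 + "MGG"

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            expand_consensus("CCGXCGG")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            expand_consensus("ACGT")

    def test_pcm_collapse(self):
        # columns: A, C, G, T counts; 25% threshold keeps two-letter sets
        pcm = np.array([
            [10, 0, 0, 5, 0],
            [0, 10, 0, 5, 0],
            [0, 0, 10, 0, 10],
            [0, 0, 0, 0, 0]])
        m = MotifModel.from_pcm("x", pcm)
        assert m.consensus == "ACGMG"

    def test_shipped_motifs_load(self):
        motifs = {m.motif_id: m.consensus for m in load_known_motifs()}
        assert motifs["prtT"] == "CCGHCGG"
        assert motifs["amyR"] == "CGG" + "N" * 8 + "MGG"


class TestScanMotif:
    def test_h_matches_a_not_g(self):
        hits = scan_motif({"chr1": "AACCGACGGTT"}, PRTT)
        assert len(hits) == 1
        assert hits.iloc[0][["start", "end", "strand"]].tolist() == [2, 9, "+"]
        # H excludes G, so CCGGCGG is no forward match; the site does
        # match the reverse-complement consensus CCGDCGG (D includes G)
        hits = scan_motif({"chr1": "AACCGGCGGTT"}, PRTT)
        assert not (hits["strand"] == "+").any()
        assert hits["strand"].tolist() == ["-"]

    def test_palindrome_reported_once_on_plus(self):
        ebox = MotifModel.from_string("ebox", "CACGTG")
        assert ebox.is_palindromic
        hits = scan_motif({"chr1": "TTCACGTGTT"}, ebox)
        assert len(hits) == 1 and hits.iloc[0]["strand"] == "+"

    def test_matches_regex_oracle_on_random_sequence(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        hits = scan_motif({"chr1": seq}, PRTT)
        pattern = re.compile("(?=(CCG[ACT]CGG))")
        rc = reverse_complement_consensus("CCGHCGG")
        rc_pattern = re.compile("(?=(CCG" + "[AGT]" + "CGG))")
        fwd = {m.start() for m in pattern.finditer(seq)}
        rev = {m.start() for m in rc_pattern.finditer(seq)} - fwd
        got_fwd = set(hits.loc[hits["strand"] == "+", "start"])
        got_rev = set(hits.loc[hits["strand"] == "-", "start"])
        assert got_fwd == fwd and got_rev == rev

    def test_revcomp_genome_consistency(self):
        """Scanning the reverse complement of the genome returns the
        same sites with coordinates reflected, and strands swapped for
        every site that matches a single strand (sites matching both
        strands stay on + under the palindrome rule)."""
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=20_000))
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        fwd = scan_motif({"c": seq}, PRTT)
        rev = scan_motif({"c": rc}, PRTT)
        reflected = sorted(len(seq) - e for e in rev["end"])
        assert reflected == sorted(fwd["start"])
        dual = {m.start() for m in re.finditer("(?=(CCG[AT]CGG))", seq)}
        rev_by_pos = {len(seq) - e: s for e, s in zip(rev["end"], rev["strand"])}
        swap = {"+": "-", "-": "+"}
        for start, strand in zip(fwd["start"], fwd["strand"]):
            if start in dual:
                assert strand == "+" and rev_by_pos[start] == "+"
            else:
                assert rev_by_pos[start] == swap[strand]

    def test_interval_restriction(self):
        seq = "AACCGACGGTT" + "T" * 50 + "CCGACGG" + "TT"
        ivals = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [12]})
        hits = scan_motif({"chr1": seq}, PRTT, intervals=ivals)
        assert len(hits) == 1 and hits.iloc[0]["start"] == 2


class TestMotifEnrichment:
    def _genome_with_sites(self, rng, n_target, n_background, target_hit_rate,
                           background_hit_rate):
        chunks, t_rows, b_rows = [], [], []
        pos = 0
        for i in range(n_target + n_background):
            s = "".join(rng.choice(list("ACT"), size=60))  # no G: no chance hits
            hit = rng.random() < (target_hit_rate if i < n_target
                                  else background_hit_rate)
            if hit:
                s = s[:20] + "CCGACGG" + s[27:]
            chunks.append(s)
            row = ("chr1", pos, pos + 60)
            (t_rows if i < n_target else b_rows).append(row)
            pos += 60
        cols = ["chrom", "start", "end"]
        return ({"chr1": "".join(chunks)}, pd.DataFrame(t_rows, columns=cols),
                pd.DataFrame(b_rows, columns=cols))

    def test_equal_sets_not_enriched(self):
        rng = np.random.default_rng(2)
        seqs, t, b = self._genome_with_sites(rng, 100, 100, 0.2, 0.2)
        res = motif_enrichment(t, b, PRTT, seqs)
        assert not res.passes and 0.01 < res.p_value

    def test_planted_enrichment_passes(self):
        rng = np.random.default_rng(3)
        seqs, t, b = self._genome_with_sites(rng, 200, 2000, 0.5, 0.01)
        res = motif_enrichment(t, b, PRTT, seqs)
        assert res.passes and res.fold_enrichment > 5 and res.p_value < 1e-12

    def test_hypergeometric_matches_exact_summation(self):
        rng = np.random.default_rng(4)
        seqs, t, b = self._genome_with_sites(rng, 30, 60, 0.5, 0.1)
        res = motif_enrichment(t, b, PRTT, seqs)
        N, n = 90, 30
        K = res.hits_target + res.hits_background
        k = res.hits_target
        from math import comb
        exact = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)
                    ) / comb(N, n)
        assert res.p_value == pytest.approx(exact, rel=1e-9)

    def test_zero_hits_degenerate(self):
        rng = np.random.default_rng(5)
        seqs, t, b = self._genome_with_sites(rng, 20, 20, 0.0, 0.0)
        res = motif_enrichment(t, b, PRTT, seqs)
        assert res.degenerate and not res.passes and res.fold_enrichment == 0.0

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            motif_enrichment(pd.DataFrame({"chrom": [], "start": [], "end": []}),
                             pd.DataFrame({"chrom": [], "start": [], "end": []}),
                             PRTT, {"chr1": "ACGT" * 10})


GENES = [
    GeneAnnotation("plus_gene", "chr1", 5000, 6000, "+"),
    GeneAnnotation("minus_gene", "chr1", 8000, 9000, "-"),
]


def _inst(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


class TestInstancesToTargets:
    def test_upstream_assignment(self):
        t = instances_to_targets(_inst([("chr1", 4495, 4505, "m")]), GENES)
        assert t["gene_id"].tolist() == ["plus_gene"]

    def test_beyond_window_unassigned(self):
        t = instances_to_targets(_inst([("chr1", 3495, 3505, "m")]), GENES)
        assert len(t) == 0

    def test_minus_strand_upstream_is_right_of_tss(self):
        t = instances_to_targets(_inst([("chr1", 9495, 9505, "m")]), GENES)
        assert t["gene_id"].tolist() == ["minus_gene"]

    def test_matches_bruteforce_window_scan(self):
        rng = np.random.default_rng(6)
        starts = rng.integers(0, 12_000, size=300)
        inst = _inst([("chr1", int(s), int(s) + 10, "m") for s in starts])
        got = instances_to_targets(inst, GENES)
        expected = []
        for s in starts:
            mid = int(s) + 5
            for g in GENES:
                lo, hi = ((g.tss - 1000, g.tss) if g.strand == "+"
                          else (g.tss + 1, g.tss + 1001))
                if lo <= mid < hi:
                    expected.append((int(s), g.gene_id))
        assert sorted(zip(got["start"], got["gene_id"])) == sorted(expected)


class TestExpressionIntegration:
    def _expr(self):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(10)],
            "log2FC": [-2.0, -1.0, -0.5, 1.0, 2.0, -3.0, 0.0, -1.5, 0.9, -1.0],
            "p": [0.01, 0.04, 0.01, 0.01, 0.2, 0.03, 0.9, 0.06, 0.01, 0.049]})

    def test_deg_rule_matches_figure_legend(self):
        """DEG = |log2FC| >= 1 and P < 0.05, by direction."""
        expr = self._expr()
        down = deg_flags(expr, "down")
        assert set(expr.loc[down, "gene_id"]) == {"g0", "g1", "g5", "g9"}
        up = deg_flags(expr, "up")
        assert set(expr.loc[up, "gene_id"]) == {"g3"}

    def test_nested_targets(self):
        expr = self._expr()
        res = integrate_expression(["g0", "g1"], expr, "down")
        assert res["overlap"] == 2
        exact = stats.hypergeom.sf(1, 10, 4, 2)
        assert res["p_value"] == pytest.approx(exact)

    def test_disjoint_targets(self):
        res = integrate_expression(["g4", "g6"], self._expr(), "down")
        assert res["overlap"] == 0

    def test_power_on_planted_enrichment(self):
        """Targets enriched 20% among DEGs (universe 5000): the overlap
        P is below 0.05 in >= 90% of replicates."""
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(5000)]
        wins = 0
        for _ in range(100)[:100]:
            degs = set(rng.choice(genes, size=500, replace=False))
            n_from_deg = 40  # 20% of a 200-gene target set from DEGs
            targets = (list(rng.choice(sorted(degs), size=n_from_deg, replace=False))
                       + list(rng.choice(sorted(set(genes) - degs), size=160,
                                         replace=False)))
            expr = pd.DataFrame({
                "gene_id": genes,
                "log2FC": [-2.0 if g in degs else 0.0 for g in genes],
                "p": 0.01})
            res = integrate_expression(targets, expr, "down")
            wins += res["p_value"] < 0.05
        assert wins >= 90
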