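import math

import numpy as np
import pytest

from poolsweep import variant_screen as vs
from poolsweep import io as psio
from poolsweep import diversity  # noqa: F401  (import order sanity)

# independent oracle: the standard genetic code written out literally
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def revcomp(s):
    return "".join(COMPLEMENT[b] for b in reversed(s))


class TestClassifySnp:
    def test_leu_to_phe(self):
        seq = "ATG" + "CTT" + "TAA"
        gene = psio.GeneModel("g", "c", "+", [(1, 9)])
        cons, aa, conserv = vs.classify_snp(seq, gene, 4, "C", "T")
        assert cons == "nonsynonymous"
        assert aa == "L2F"

    def test_synonymous_third_position(self):
        seq = "ATG" + "CTT" + "TAA"
        gene = psio.GeneModel("g", "c", "+", [(1, 9)])
        cons, aa, conserv = vs.classify_snp(seq, gene, 6, "T", "G")
        assert cons == "synonymous" and aa is None

    def test_minus_strand_hand_translated(self):
        # minus-strand gene: CDS read as revcomp of genomic 1..9
        # genomic: TTACATCAT -> revcomp ATGATGTAA = M M *
        seq = "TTACATCAT"
        gene = psio.GeneModel("g", "c", "-", [(1, 9)])
        # genomic pos 5 (A) is CDS offset 9-1-4=4, codon 2 position 2 (ATG)
        # A->G genomic means T->C on the coding strand: ATG -> ACG (M -> T)
        cons, aa, conserv = vs.classify_snp(seq, gene, 5, "A", "G")
        assert cons == "nonsynonymous"
        assert aa == "M2T"

    def test_noncoding_outside_cds(self):
        seq = "ATGCTTTAAG"
        gene = psio.GeneModel("g", "c", "+", [(1, 9)])
        assert vs.classify_snp(seq, gene, 10, "G", "A")[0] == "noncoding"

    def test_reference_mismatch_raises(self):
        seq = "ATGCTTTAA"
        gene = psio.GeneModel("g", "c", "+", [(1, 9)])
        with pytest.raises(vs.ReferenceMismatchError):
            vs.classify_snp(seq, gene, 4, "G", "T")

    def test_reference_n_excluded(self):
        seq = "ATGNTTTAA"
        gene = psio.GeneModel("g", "c", "+", [(1, 9)])
        assert vs.classify_snp(seq, gene, 4, "N", "T")[0] == "noncoding"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exhaustive_codon_oracle(self, strand):
        # all 61 sense codons x 3 positions x 3 substitutions on both strands
        for codon, ref_aa in CODON_TABLE.items():
            if ref_aa == "*":
                continue
            coding = "ATG" + codon + "TAA"
            if strand == "+":
                seq = coding
                gene = psio.GeneModel("g", "c", "+", [(1, 9)])
            else:
                seq = revcomp(coding)
                gene = psio.GeneModel("g", "c", "-", [(1, 9)])
            for within in range(3):
                cds_pos = 3 + within           # 0-based within coding
                if strand == "+":
                    genomic_pos = cds_pos + 1
                else:
                    genomic_pos = 9 - cds_pos
                ref_base = seq[genomic_pos - 1]
                for alt_base in "ACGT":
                    if alt_base == ref_base:
                        continue
                    coding_alt = alt_base if strand == "+" else COMPLEMENT[alt_base]
                    alt_codon = (
                        codon[:within] + coding_alt + codon[within + 1:]
                    )
                    want_aa = CODON_TABLE[alt_codon]
                    cons, aa, conserv = vs.classify_snp(
                        seq, gene, genomic_pos, ref_base, alt_base)
                    if want_aa == ref_aa:
                        assert cons == "synonymous", (codon, within, alt_base)
                        assert aa is None
                    else:
                        assert cons == "nonsynonymous", (codon, within, alt_base)
                        assert aa == f"{ref_aa}2{want_aa}"


class TestConservative:
    def test_leu_phe_is_borderline_conservative(self):
        # BLOSUM62(L, F) = 0 -> conservative at the default >= 0 threshold
        assert vs.is_conservative("L", "F")

    def test_asp_lys_nonconservative(self):
        assert not vs.is_conservative("D", "K")

    def test_threshold_configurable(self):
        assert not vs.is_conservative("L", "F", threshold=1.0)


class TestAltReadFraction:
    def test_all_reads(self):
        assert vs.alt_read_fraction([0, 50, 0, 0], "T") == 1.0

    def test_partial(self):
        assert vs.alt_read_fraction([9, 41, 0, 0], "T") == pytest.approx(0.82)

    def test_zero(self):
        assert vs.alt_read_fraction([50, 0, 0, 0], "T") == 0.0

    def test_no_coverage_nan(self):
        assert math.isnan(vs.alt_read_fraction([0, 0, 0, 0], "T"))


def build_mat(rows, ref_bases, chrom="c"):
    counts = np.zeros((len(rows), len(rows[0]), 6), dtype=np.int64)
    counts[:, :, :4] = np.asarray(rows)
    return psio.SyncMatrix(
        chroms=np.array([chrom] * len(rows), dtype=object),
        pos=np.arange(1, len(rows) + 1),
        ref=np.array(list(ref_bases), dtype=object),
        counts=counts,
    )


class TestScreenRegion:
    def test_empty_region(self):
        mat = build_mat([[[50, 0, 0, 0]]], "A")
        assert vs.screen_region(("c", 1, 1), mat, [], {"c": "A"}) == []

    def test_synonymous_only_fixture_filters_out(self):
        # site 6 is the third base of codon CTT; T->C is synonymous
        seq = "ATGCTTTAA"
        gene = psio.GeneModel("g", "c", "+", [(1, 9)])
        base_idx = {"A": 0, "T": 1, "C": 2, "G": 3}
        rows = []
        for b in seq:                  # monomorphic reads on the reference base
            row = [[0, 0, 0, 0]]
            row[0][base_idx[b]] = 50
            rows.append(row)
        rows[5] = [[0, 25, 25, 0]]     # T=25, C=25 at pos 6
        mat = build_mat(rows, seq)
        calls = vs.screen_region(("c", 1, 9), mat, [gene], {"c": seq})
        assert len(calls) == 1
        assert calls[0].consequence == "synonymous"
        assert [c for c in calls if c.consequence == "nonsynonymous"] == []

    def test_intergenic_call(self):
        mat = build_mat([[[25, 25, 0, 0]]], "A")
        (call,) = vs.screen_region(("c", 1, 1), mat, [], {"c": "A"})
        assert call.gene_id == "intergenic"
        assert call.consequence == "noncoding"

    def test_kdr_like_fixed_snp_on_simulation(self, sweep_sim):
        cfg, (mat, genes, ref, truth) = sweep_sim
        row = truth.snps[truth.snps["kind"] == "fixed"].iloc[0]
        pos = int(row["pos"])
        kdr = [g for g in genes if g.gene_id == "gene_kdr"][0]
        calls = vs.screen_region(
            ("scaffold_1", pos - 10, pos + 10), mat, genes,
            {"scaffold_1": ref}, min_count=2,
        )
        nonsyn = [c for c in calls if c.consequence == "nonsynonymous"]
        assert len(nonsyn) == 1
        call = nonsyn[0]
        assert call.pos == pos and call.gene_id == kdr.gene_id
        assert call.aa_change.startswith("L") and call.aa_change.endswith("F")
        for frac in call.fractions:
            assert frac == pytest.approx(1.0)

    def test_fractions_match_truth_within_binomial_error(self, sweep_sim):
        cfg, (mat, genes, ref, truth) = sweep_sim
        row = truth.snps[truth.snps["kind"] == "outlier"].iloc[0]
        pos = int(row["pos"])
        calls = vs.screen_region(
            ("scaffold_1", pos, pos), mat, genes, {"scaffold_1": ref},
            min_count=2,
        )
        call = [c for c in calls if c.alt == row["alt"]][0]
        for p, frac in enumerate(call.fractions):
            pool_frac = row[f"pool_count_{p}"] / cfg.two_n
            tol = 4 * math.sqrt(max(pool_frac * (1 - pool_frac), 0.01) / 50)
            assert frac == pytest.approx(pool_frac, abs=tol)

    def test_frame_rendering(self, sweep_sim):
        cfg, (mat, genes, ref, truth) = sweep_sim
        pos = int(truth.snps[truth.snps["kind"] == "fixed"]["pos"].iloc[0])
        calls = vs.screen_region(
            ("scaffold_1", pos - 5, pos + 5), mat, genes, {"scaffold_1": ref})
        df = vs.calls_to_frame(calls)
        assert {"chrom", "pos", "consequence", "fractions"} <= set(df.columns)
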