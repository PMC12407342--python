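import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_scan
from kranz.motifs import (
    IUPAC,
    MotifConsensus,
    call_environment_triggered,
    call_predominant,
    count_elements,
    count_matches,
    normalize_frequency,
    reverse_complement,
    scan_promoters,
)


def _links(rows):
    out = []
    for i, (element, gene, fam, ct, cond) in enumerate(rows):
        out.append({
            "element_id": element, "chromosome": "chr1", "start": 10 * i,
            "end": 10 * i + 5, "gene_id": gene, "motif_family": fam,
            "cell_type": ct, "condition": cond,
        })
    return pd.DataFrame(out)


class TestCounting:
    def test_element_vs_occurrence_mode(self):
        links = _links([("e1", "g1", "NAC", "IMC", "terrestrial")] * 3)
        c_el = count_elements(links, ["g1"], count_mode="element")
        c_oc = count_elements(links, ["g1"], count_mode="occurrence")
        assert c_el.loc["NAC", ("IMC", "terrestrial")] == 1
        assert c_oc.loc["NAC", ("IMC", "terrestrial")] == 3

    def test_single_row_and_order_invariance(self):
        rows = [("e1", "g1", "NAC", "IMC", "terrestrial"),
                ("e2", "g1", "bZIP", "KC", "terrestrial"),
                ("e3", "g2", "NAC", "IMC", "submerged")]
        links = _links(rows)
        c1 = count_elements(links, ["g1", "g2"])
        c2 = count_elements(links.iloc[::-1].reset_index(drop=True), ["g1", "g2"])
        pd.testing.assert_frame_equal(c1, c2)
        assert c1.loc["bZIP", ("KC", "terrestrial")] == 1
        assert c1.to_numpy().sum() == 3

    def test_element_mode_bounded_by_occurrence_mode(self):
        rng = np.random.default_rng(0)
        rows = [(f"e{rng.integers(5)}", f"g{rng.integers(3)}",
                 rng.choice(["NAC", "bZIP"]), "IMC", "terrestrial")
                for _ in range(50)]
        links = _links(rows)
        genes = ["g0", "g1", "g2"]
        el = count_elements(links, genes, count_mode="element")
        oc = count_elements(links, genes, count_mode="occurrence")
        assert (el.to_numpy() <= oc.to_numpy()).all()

    def test_empty_gene_set_rejected_and_zero_match_warns(self):
        links = _links([("e1", "g1", "NAC", "IMC", "terrestrial")])
        with pytest.raises(ValueError):
            count_elements(links, [])
        zero = count_elements(links, ["unknown_gene"])
        assert (zero.to_numpy() == 0).all()


class TestNormalization:
    def test_column_sums(self):
        counts = pd.DataFrame({"grp": [2, 2], "grp2": [3, 1]}, index=["NAC", "bZIP"])
        freq = normalize_frequency(counts)
        assert np.allclose(freq.rates["grp"], [0.5, 0.5])
        assert np.allclose(freq.rates["grp2"], [0.75, 0.25])

    def test_three_way_column(self):
        counts = pd.DataFrame({"g": [3, 1, 0]}, index=["a", "b", "c"])
        freq = normalize_frequency(counts)
        assert np.allclose(freq.rates["g"], [0.75, 0.25, 0.0])

    def test_all_zero_column_flagged_not_nan(self):
        counts = pd.DataFrame({"g1": [1, 1], "g2": [0, 0]}, index=["a", "b"])
        freq = normalize_frequency(counts)
        assert freq.degenerate == {"g2"}
        assert np.allclose(freq.rates["g2"], 0.0)
        assert not freq.rates.isna().any().any()


class TestCalls:
    def test_predominant_at_exemplar_rates(self):
        # NAC at 24.2% is the maximal family in the IMC column
        rates = pd.DataFrame({
            "IMC": [0.242, 0.05, 0.354, 0.354],
            "KC": [0.099, 0.348, 0.277, 0.276],
        }, index=["NAC", "bZIP", "x1", "x2"])
        calls = call_predominant(normalize_frequency((rates * 1000).astype(int)))
        imc = calls[calls["group"] == "IMC"]
        kc = calls[calls["group"] == "KC"]
        assert set(imc["family"]) == {"x1", "x2"}  # tie reported lexicographically
        assert list(imc["family"]) == ["x1", "x2"]
        assert list(kc["family"]) == ["bZIP"]

    def test_no_call_below_threshold(self):
        rates = pd.DataFrame({"g": [0.05] * 20}, index=[f"f{i:02d}" for i in range(20)])
        counts = (rates * 100).astype(int)
        calls = call_predominant(normalize_frequency(counts), tau_pred=0.10)
        assert len(calls) == 0

    def test_environment_triggered_exemplars(self):
        # (21.6%, 0%) and (18%, 5%) trigger; (8%, 0%) does not
        fams = ["Homeobox", "MYB-related", "weak", "stable"]
        f1 = normalize_frequency(pd.DataFrame(
            {"IMC": [216, 180, 80, 524]}, index=fams))
        f2 = normalize_frequency(pd.DataFrame(
            {"IMC": [0, 50, 0, 950]}, index=fams))
        calls = call_environment_triggered(f1, f2)
        assert list(calls["family"]) == ["Homeobox", "MYB-related"]

    def test_axis_mismatch_rejected(self):
        f1 = normalize_frequency(pd.DataFrame({"a": [1]}, index=["x"]))
        f2 = normalize_frequency(pd.DataFrame({"b": [1]}, index=["x"]))
        with pytest.raises(ValueError):
            call_environment_triggered(f1, f2)


class TestScanner:
    def test_overlapping_matches(self):
        assert count_matches("AAAA", "AA") == 3

    def test_palindrome_counted_per_strand(self):
        scan = scan_promoters({"g": "ACGT"}, [MotifConsensus("f", ["ACGT"])],
                              strand_mode="both")
        assert scan.loc["f", "g"] == 2
        fwd = scan_promoters({"g": "ACGT"}, [MotifConsensus("f", ["ACGT"])],
                             strand_mode="forward")
        assert fwd.loc["f", "g"] == 1

    def test_pattern_longer_than_sequence(self):
        assert count_matches("ACGTA", "N" * 12) == 0

    def test_n_in_sequence_never_matches(self):
        assert count_matches("ANA", "NNN") == 0
        assert count_matches("AAA", "NNN") == 1

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError):
            count_matches("ACGT", "AXGT")
        with pytest.raises(ValueError):
            MotifConsensus("f", ["AZ"])

    def test_matches_brute_force_oracle_random(self):
        rng = np.random.default_rng(42)
        symbols = list(IUPAC)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGTN"), size=rng.integers(5, 60)))
            pat = "".join(rng.choice(symbols, size=rng.integers(1, 6)))
            assert count_matches(seq, pat) == brute_force_scan(seq, pat)
            # both-strand scan equals forward + reverse-complement oracle counts
            scan = scan_promoters({"g": seq}, [MotifConsensus("f", [pat])],
                                  strand_mode="both")
            expected = brute_force_scan(seq, pat) + brute_force_scan(
                seq, reverse_complement(pat))
            assert scan.loc["f", "g"] == expected

    def test_reverse_complement_involution(self):
        assert reverse_complement("ACGTRYSWKMBDHVN") == "NBDHVKMWSRYACGT"
        for s in ("ACGT", "TTTTA", "RYSWKM"):
            assert reverse_complement(reverse_complement(s)) == s
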