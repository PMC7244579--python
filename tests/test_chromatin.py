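"""TSS-window linkage and its frequency/enrichment/concordance statistics."""

import numpy as np
import pandas as pd
import pytest

from omixlink import chromatin
from omixlink.integration import derive_status
from omixlink.simulate import simulate_annotation, simulate_peaks
from tests.conftest import make_peaks


def brute_force_links(peaks, annotation, window_bp):
    half = window_bp // 2
    out = set()
    for p in peaks.itertuples():
        for g in annotation.itertuples():
            lo, hi = max(0, g.tss - half), g.tss + half
            if p.chrom == g.chrom and p.start < hi and p.end > lo:
                out.add((g.gene_id, p.peak_id))
    return out


class TestLinkPeaksToGenes:
    @pytest.mark.parametrize(
        "start,end,linked",
        [
            (30_000, 30_100, True),   # starts exactly at window edge
            (29_900, 30_000, False),  # ends at half-open window start
            (69_990, 70_050, True),   # partial overlap at far edge
            (70_000, 70_100, False),  # starts at half-open window end
        ],
    )
    def test_window_boundaries(self, start, end, linked):
        annotation = pd.DataFrame(
            {"gene_id": ["g1"], "chrom": ["chr1"], "tss": [50_000],
             "strand": ["+"]}
        )
        peaks = make_peaks([("chr1", start, end, "gained")])
        links = chromatin.link_peaks_to_genes(peaks, annotation, window_bp=40_000)
        assert (len(links.links) == 1) is linked

    def test_peak_links_multiple_genes(self):
        annotation = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "chrom": ["chr1"] * 2,
             "tss": [50_000, 60_000], "strand": ["+", "+"]}
        )
        peaks = make_peaks([("chr1", 55_000, 55_100, "gained")])
        links = chromatin.link_peaks_to_genes(peaks, annotation)
        assert set(links.links["gene_id"]) == {"g1", "g2"}

    def test_missing_chromosome_unlinked(self, annotation):
        peaks = make_peaks([("chrX", 100, 200, "gained")])
        links = chromatin.link_peaks_to_genes(peaks, annotation)
        assert len(links.links) == 0

    def test_odd_window_rejected(self, annotation):
        peaks = make_peaks([("chr1", 100, 200, "gained")])
        with pytest.raises(ValueError):
            chromatin.link_peaks_to_genes(peaks, annotation, window_bp=40_001)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n_genes = int(rng.integers(3, 50))
            n_peaks = int(rng.integers(1, 200))
            annotation = pd.DataFrame(
                {
                    "gene_id": [f"g{i}" for i in range(n_genes)],
                    "chrom": rng.choice(["chr1", "chr2"], size=n_genes),
                    "tss": rng.integers(0, 200_000, size=n_genes),
                    "strand": rng.choice(["+", "-"], size=n_genes),
                }
            )
            starts = rng.integers(0, 220_000, size=n_peaks)
            peaks = make_peaks(
                [
                    (c, s, s + w, "gained")
                    for c, s, w in zip(
                        rng.choice(["chr1", "chr2"], size=n_peaks),
                        starts,
                        rng.integers(1, 5000, size=n_peaks),
                    )
                ]
            )
            links = chromatin.link_peaks_to_genes(peaks, annotation, 40_000)
            got = set(map(tuple, links.links[["gene_id", "peak_id"]].values))
            assert got == brute_force_links(peaks, annotation, 40_000)


class TestStatusFrequency:
    def _links(self, n_gained_per_gene, annotation_genes):
        annotation = pd.DataFrame(
            {
                "gene_id": annotation_genes,
                "chrom": "chr1",
                "tss": np.arange(len(annotation_genes)) * 100_000 + 50_000,
                "strand": "+",
            }
        )
        rows = []
        for g, n in zip(annotation_genes, n_gained_per_gene):
            tss = annotation.set_index("gene_id").loc[g, "tss"]
            for i in range(n):
                rows.append(("chr1", tss + i * 10, tss + i * 10 + 5, "gained"))
        return chromatin.link_peaks_to_genes(make_peaks(rows), annotation)

    def test_all_stable_genes_zero_up_fraction(self):
        genes = [f"g{i}" for i in range(8)]
        links = self._links([0, 1, 1, 2, 2, 3, 3, 4], genes)
        table = pd.DataFrame(
            {"feature_id": genes, "log2fc": 0.0, "p_value": 1.0,
             "fdr": 1.0, "status": "stable"}
        )
        freq = chromatin.status_frequency_by_links(links, table)
        assert (freq["up"].dropna() == 0).all()

    def test_proportions_sum_to_one(self):
        genes = [f"g{i}" for i in range(12)]
        links = self._links([0, 0, 1, 1, 1, 2, 2, 3, 3, 4, 5, 0], genes)
        table = pd.DataFrame(
            {
                "feature_id": genes[:10],  # two genes not expressed
                "log2fc": [1.0] * 5 + [-1.0] * 5,
                "p_value": 0.01,
                "fdr": 0.01,
            }
        )
        table = derive_status(table)
        freq = chromatin.status_frequency_by_links(links, table)
        sums = freq[["up", "down", "stable", "not_expressed"]].sum(axis=1)
        assert np.allclose(sums.dropna(), 1.0)

    def test_up_fraction_increases_with_gained_peaks(self):
        # planted coupling: gained peaks preferentially near upregulated genes
        hits = 0
        for seed in range(15):
            annotation = simulate_annotation(n_genes=200, seed=seed)
            up = set(annotation["gene_id"][:60])
            peaks, _ = simulate_peaks(
                annotation, up, p_gain_near_up=0.9, p_gain_background=0.1,
                n_peaks=600, seed=seed,
            )
            links = chromatin.link_peaks_to_genes(peaks, annotation)
            table = pd.DataFrame(
                {
                    "feature_id": annotation["gene_id"],
                    "log2fc": [2.0 if g in up else 0.0
                               for g in annotation["gene_id"]],
                    "p_value": 0.01,
                    "fdr": 0.01,
                    "status": ["up" if g in up else "stable"
                               for g in annotation["gene_id"]],
                }
            )
            freq = chromatin.status_frequency_by_links(links, table)
            ups = freq["up"].to_numpy()
            if np.all(np.diff(ups[~np.isnan(ups)]) > 0):
                hits += 1
        assert hits >= 12  # >= 80% of seeds show a strictly increasing trend


class TestEffectByGainedCount:
    def _make(self, means, n=50, sd=0.5, seed=0):
        rng = np.random.default_rng(seed)
        genes, rows, effects = [], [], []
        for stratum, mu in enumerate(means):
            for i in range(n):
                g = f"g{stratum}_{i}"
                genes.append(g)
                effects.append(rng.normal(mu, sd))
                rows.append((g, stratum))
        annotation = pd.DataFrame(
            {
                "gene_id": genes,
                "chrom": "chr1",
                "tss": np.arange(len(genes)) * 100_000 + 50_000,
                "strand": "+",
            }
        )
        peak_rows = []
        lookup = annotation.set_index("gene_id")["tss"]
        for g, stratum in rows:
            for i in range(stratum):
                t = lookup[g]
                peak_rows.append(("chr1", t + i * 10, t + i * 10 + 5, "gained"))
        links = chromatin.link_peaks_to_genes(make_peaks(peak_rows), annotation)
        table = pd.DataFrame(
            {"feature_id": genes, "log2fc": effects, "p_value": 0.01, "fdr": 0.01}
        )
        return links, table

    def test_planted_trend_detected(self):
        detected = 0
        for seed in range(10):
            links, table = self._make([0.0, 0.5, 1.0, 1.5], seed=seed)
            out = chromatin.effect_by_gained_count(
                links, table, n_permutations=2000, seed=seed
            )
            if out["trend_p"] < 0.001:
                detected += 1
        assert detected >= 9

    def test_null_rejection_rate_calibrated(self):
        rejections = 0
        n_seeds = 40
        for seed in range(n_seeds):
            links, table = self._make([0.0, 0.0, 0.0, 0.0], n=25, seed=seed)
            out = chromatin.effect_by_gained_count(
                links, table, n_permutations=400, seed=seed
            )
            rejections += out["trend_p"] < 0.05
        assert rejections / n_seeds <= 0.125  # ~0.05 nominal plus binomial slack

    def test_single_stratum_rejected(self):
        links, table = self._make([1.0])
        with pytest.raises(ValueError):
            chromatin.effect_by_gained_count(links, table)


class TestGainedEnrichmentChi2:
    def _links_universe(self, n_in_with, n_in, n_out_with, n_out):
        genes = [f"g{i}" for i in range(n_in + n_out)]
        module = set(genes[:n_in])
        with_gained = genes[:n_in_with] + genes[n_in: n_in + n_out_with]
        annotation = pd.DataFrame(
            {"gene_id": genes, "chrom": "chr1",
             "tss": np.arange(len(genes)) * 100_000 + 50_000, "strand": "+"}
        )
        lookup = annotation.set_index("gene_id")["tss"]
        rows = [("chr1", lookup[g], lookup[g] + 5, "gained") for g in with_gained]
        links = chromatin.link_peaks_to_genes(make_peaks(rows), annotation)
        return links, module, set(genes)

    def test_hand_computed_chi2(self):
        # 2x2 table [[30,70],[10,190]]: chi2 = 300*5000^2/(100*200*40*260)
        links, module, universe = self._links_universe(30, 100, 10, 200)
        chi2, p_one, table = chromatin.gained_enrichment_chi2(links, module, universe)
        assert table.tolist() == [[30, 70], [10, 190]]
        assert chi2 == pytest.approx(36.0576923, rel=1e-6)
        assert p_one < 1e-8

    def test_no_signal_gives_half(self):
        links, module, universe = self._links_universe(20, 100, 20, 100)
        chi2, p_one, _ = chromatin.gained_enrichment_chi2(links, module, universe)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p_one == pytest.approx(0.5)

    def test_depleted_module_above_half(self):
        links, module, universe = self._links_universe(5, 100, 60, 200)
        _, p_one, _ = chromatin.gained_enrichment_chi2(links, module, universe)
        assert p_one > 0.5

    def test_zero_margin_suggests_fisher(self):
        links, module, universe = self._links_universe(0, 100, 0, 200)
        with pytest.raises(ValueError, match="Fisher"):
            chromatin.gained_enrichment_chi2(links, module, universe)


class TestConcordance:
    def _tables(self, protein_fc, mrna_fc, fdr=0.01):
        n = len(mrna_fc)
        ids = [f"g{i}" for i in range(n)]
        mrna = pd.DataFrame(
            {"feature_id": ids, "log2fc": mrna_fc, "p_value": fdr, "fdr": fdr}
        )
        prot = pd.DataFrame(
            {"feature_id": ids, "log2fc": protein_fc, "p_value": fdr, "fdr": fdr}
        )
        return mrna, prot

    def test_identity_gives_r2_one(self):
        rng = np.random.default_rng(0)
        fc = np.concatenate([rng.uniform(1, 3, 20), rng.uniform(-3, -1, 20)])
        mrna, prot = self._tables(fc.copy(), fc)
        out = chromatin.mrna_protein_concordance(mrna, prot)
        up = out.set_index("mrna_category")
        assert up.loc["up", "r2"] == pytest.approx(1.0)
        assert up.loc["down", "r2"] == pytest.approx(1.0)

    def test_threshold_edge_excluded(self):
        mrna, prot = self._tables([1.0, 1.0, 1.0], [0.58, 0.6, 2.0])
        mrna["log2fc"] = [0.58, 0.6, 2.0]
        out = chromatin.mrna_protein_concordance(mrna, prot)
        up_n = out.set_index("mrna_category").loc["up", "n"]
        assert up_n == 2  # log2fc exactly 0.58 is not "up"

    def test_r2_matches_signal_noise_ratio(self):
        # protein = 0.8 * mrna + noise; r2 -> var(signal)/(var(signal)+var(noise))
        rng = np.random.default_rng(1)
        mrna_fc = rng.uniform(1.0, 4.0, 400)
        noise_sd = 0.5
        prot_fc = 0.8 * mrna_fc + rng.normal(0, noise_sd, 400)
        expected = (0.8**2 * np.var(mrna_fc)) / (
            0.8**2 * np.var(mrna_fc) + noise_sd**2
        )
        mrna, prot = self._tables(prot_fc, mrna_fc)
        out = chromatin.mrna_protein_concordance(mrna, prot)
        r2 = out.set_index("mrna_category").loc["up", "r2"]
        assert r2 == pytest.approx(expected, abs=0.15)

    def test_small_category_gives_nan(self):
        mrna, prot = self._tables([1.0, -1.0], [1.0, -1.0])
        out = chromatin.mrna_protein_concordance(mrna, prot)
        assert np.isnan(out.set_index("mrna_category").loc["up", "r2"])
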