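import pytest

from conftest import make_clone, make_peptide
from seromap.enrichment import EnrichmentResult, compute_enrichment
from seromap.errors import ValidationError
from seromap.mapping import MappingResult, map_peptides
from seromap.repertoire import group_clones
from seromap.stats import (
    quantify_clones,
    render_report,
    summarize_repertoire,
    summary_tables,
)


def _enr(peptide, elution_mean):
    return EnrichmentResult(
        peptide=peptide,
        elution_mean=elution_mean,
        flow_through_mean=1.0,
        n_detected_elution=2,
        n_detected_flow_through=2,
        fold_change=elution_mean,
        is_antigen_specific=True,
    )


def _informative(peptide, group_key, cdr3=True):
    return MappingResult(
        peptide=peptide,
        hits=(),
        clone_groups_hit=frozenset([group_key]),
        classification="informative",
        informative_cdr3=cdr3,
    )


def _multi(peptide, group_keys):
    return MappingResult(
        peptide=peptide,
        hits=(),
        clone_groups_hit=frozenset(group_keys),
        classification="multi_mapped",
        informative_cdr3=False,
    )


@pytest.fixture
def small_repertoire():
    clones = [
        make_clone("a", "EVQAKDYWGQGAR", "AKDYWGQGAR", isotype="IgG1",
                   v_call="V1", d_call="D1", j_call="J1", read_count=6),
        make_clone("b", "DVQAKEYWGQGAWQEST", "AKEYWGQGAWQEST", isotype="IgM",
                   v_call="V2", d_call=None, j_call="J2", read_count=3),
        make_clone("c", "MVQAKFYWGQGAR", "AKFYWGQGAR", isotype="IgG1",
                   v_call="V1", d_call="D2", j_call="J1", read_count=1),
    ]
    return clones, group_clones(clones)


class TestQuantifyClones:
    def test_intensities_sum_within_group(self, small_repertoire):
        clones, groups = small_repertoire
        mapping = [
            _informative("PEP1", "AKDYWGQGAR"),
            _informative("PEP2", "AKDYWGQGAR", cdr3=False),
        ]
        enrichment = [_enr("PEP1", 10.0), _enr("PEP2", 5.0)]
        (quant,) = quantify_clones(mapping, enrichment, groups)
        assert quant.summed_intensity == 15.0
        assert quant.n_informative_peptides == 2
        assert quant.n_cdr3_peptides == 1
        assert quant.bcr_frequency == pytest.approx(6 / 10)

    def test_multi_mapped_only_gives_empty_output(self, small_repertoire):
        _, groups = small_repertoire
        mapping = [_multi("PEP1", ["AKDYWGQGAR", "AKFYWGQGAR"])]
        assert quantify_clones(mapping, [_enr("PEP1", 10.0)], groups) == []

    def test_unknown_group_errors(self, small_repertoire):
        _, groups = small_repertoire
        with pytest.raises(ValidationError, match="unknown group"):
            quantify_clones([_informative("PEP1", "NOSUCH")], [_enr("PEP1", 1.0)], groups)

    def test_mean_roll_up_option(self, small_repertoire):
        _, groups = small_repertoire
        mapping = [_informative("P1", "AKDYWGQGAR"), _informative("P2", "AKDYWGQGAR")]
        enrichment = [_enr("P1", 10.0), _enr("P2", 6.0)]
        (quant,) = quantify_clones(mapping, enrichment, groups, roll_up="mean")
        assert quant.summed_intensity == 8.0

    def test_conservation_on_pipeline_objects(self, design_2x2, small_repertoire):
        """Total clone intensity equals total informative-peptide elution mean."""
        clones, groups = small_repertoire
        peptides = [
            make_peptide("AKDYWGQGAR", [50, 70], [1, 1]),   # clone a CDR3
            make_peptide("AKEYWGQGAWQEST", [30, 30], [1, 1]),  # clone b CDR3
            make_peptide("YWGQGAR", [40, 40], [1, 1]),      # shared a/c
        ]
        enrichment = compute_enrichment(peptides, design_2x2)
        specific = [r.peptide for r in enrichment if r.is_antigen_specific]
        mapping = map_peptides(specific, clones, groups)
        quants = quantify_clones(mapping, enrichment, groups)
        informative = {r.peptide for r in mapping if r.classification == "informative"}
        expected = sum(r.elution_mean for r in enrichment if r.peptide in informative)
        assert sum(q.summed_intensity for q in quants) == pytest.approx(expected, rel=1e-9)


class TestSummarizeRepertoire:
    def test_single_isotype_distribution(self, small_repertoire):
        clones, groups = small_repertoire
        mapping = [_informative("P1", "AKDYWGQGAR")]
        quants = quantify_clones(mapping, [_enr("P1", 1.0)], groups)
        summary = summarize_repertoire(quants, groups, clones)
        assert summary.isotype_distribution == {"IgG1": 1.0}

    def test_cdr3_length_histogram(self, small_repertoire):
        clones, groups = small_repertoire
        mapping = [
            _informative("P1", "AKDYWGQGAR"),       # length 10
            _informative("P2", "AKFYWGQGAR"),       # length 10
            _informative("P3", "AKEYWGQGAWQEST"),   # length 14
        ]
        enrichment = [_enr(p, 1.0) for p in ("P1", "P2", "P3")]
        quants = quantify_clones(mapping, enrichment, groups)
        summary = summarize_repertoire(quants, groups, clones)
        assert summary.cdr3_length_histogram == {10: 2, 14: 1}
        assert sum(summary.isotype_distribution.values()) == pytest.approx(1.0)

    def test_missing_d_call_excluded_from_d_tables(self, small_repertoire):
        clones, groups = small_repertoire
        mapping = [
            _informative("P1", "AKDYWGQGAR"),
            _informative("P2", "AKEYWGQGAWQEST"),  # clone b has no D call
        ]
        enrichment = [_enr(p, 1.0) for p in ("P1", "P2")]
        quants = quantify_clones(mapping, enrichment, groups)
        summary = summarize_repertoire(quants, groups, clones)
        assert sum(summary.gene_usage["v"].values()) == 2
        assert sum(summary.gene_usage["d"].values()) == 1
        assert summary.n_groups_missing_d == 1
        assert summary.gene_usage["vdj"] == {"V1|D1|J1": 1}

    def test_combined_usage_bounded_by_label_products(self, small_repertoire):
        clones, groups = small_repertoire
        mapping = [
            _informative("P1", "AKDYWGQGAR"),
            _informative("P2", "AKFYWGQGAR"),
        ]
        enrichment = [_enr(p, 1.0) for p in ("P1", "P2")]
        quants = quantify_clones(mapping, enrichment, groups)
        summary = summarize_repertoire(quants, groups, clones)
        n_v = len(summary.gene_usage["v"])
        n_d = len(summary.gene_usage["d"])
        n_j = len(summary.gene_usage["j"])
        assert len(summary.gene_usage["vdj"]) <= n_v * n_d * n_j

    def test_bcr_frequencies_over_whole_repertoire_sum_to_one(self, small_repertoire):
        clones, groups = small_repertoire
        mapping = [_informative(f"P{i}", g.group_key) for i, g in enumerate(groups)]
        enrichment = [_enr(f"P{i}", 1.0) for i in range(len(groups))]
        quants = quantify_clones(mapping, enrichment, groups)
        assert sum(q.bcr_frequency for q in quants) == pytest.approx(1.0, abs=1e-9)


class TestRenderReport:
    def _summary(self, small_repertoire):
        clones, groups = small_repertoire
        mapping = [_informative("P1", "AKDYWGQGAR"), _informative("P2", "AKEYWGQGAWQEST")]
        enrichment = [_enr(p, 2.0) for p in ("P1", "P2")]
        quants = quantify_clones(mapping, enrichment, groups)
        return summarize_repertoire(quants, groups, clones)

    def test_emits_expected_tables(self, tmp_path, small_repertoire):
        summary = self._summary(small_repertoire)
        written = render_report(summary, tmp_path, plots=False)
        tsvs = sorted(p.name for p in tmp_path.glob("*.tsv"))
        assert tsvs == [
            "cdr3_length.tsv",
            "intensity_vs_frequency.tsv",
            "isotype_distribution.tsv",
            "usage_d.tsv",
            "usage_dj.tsv",
            "usage_j.tsv",
            "usage_v.tsv",
            "usage_vd.tsv",
            "usage_vdj.tsv",
            "usage_vj.tsv",
        ]
        assert len(written) == 10

    def test_empty_summary_writes_headers_only_no_images(self, tmp_path, small_repertoire):
        clones, groups = small_repertoire
        summary = summarize_repertoire([], groups, clones)
        render_report(summary, tmp_path, plots=True)
        assert not list(tmp_path.glob("*.png"))
        for path in tmp_path.glob("*.tsv"):
            assert len(path.read_text().splitlines()) == 1  # header only

    def test_rerun_is_byte_identical(self, tmp_path, small_repertoire):
        summary = self._summary(small_repertoire)
        render_report(summary, tmp_path / "one", plots=False)
        render_report(summary, tmp_path / "two", plots=False)
        for path in sorted((tmp_path / "one").glob("*.tsv")):
            assert path.read_bytes() == (tmp_path / "two" / path.name).read_bytes()

    def test_plots_rendered_for_nonempty_summary(self, tmp_path, small_repertoire):
        summary = self._summary(small_repertoire)
        render_report(summary, tmp_path, plots=True)
        pngs = {p.name for p in tmp_path.glob("*.png")}
        assert "isotype_distribution.png" in pngs
        assert "intensity_vs_frequency.png" in pngs

    def test_tables_match_summary_contents(self, small_repertoire):
        summary = self._summary(small_repertoire)
        tables = summary_tables(summary)
        assert list(tables["isotype_distribution"]["isotype"]) == sorted(
            summary.isotype_distribution
        )
        assert tables["intensity_vs_frequency"]["summed_intensity"].sum() == pytest.approx(
            sum(q.summed_intensity for q in summary.clone_quants)
        )
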