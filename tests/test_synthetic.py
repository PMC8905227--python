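import numpy as np
import pandas as pd
import pytest

from lincforge.classify import gc_content
from lincforge.synthetic import (
    SimulationConfig,
    config_hash,
    generate_counts,
    generate_genome,
    generate_null_counts,
    make_amplicon,
)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(de_fraction=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(dispersion=-0.1)
    with pytest.raises(ValueError):
        SimulationConfig(n_lnc_u=10, n_homolog_pairs=10)


def test_truth_table_schema_and_counts(genome, default_config):
    truth = genome.truth
    cfg = default_config
    required = {
        "feature_id", "feature_type", "chromosome", "true_class_code", "true_coding",
        "fail_rule", "true_de", "true_log2fc", "homolog_partner", "syntenic_truth",
        "cluster_label",
    }
    assert required <= set(truth.columns)
    assert truth.feature_id.is_unique
    vc = truth.feature_type.value_counts()
    assert vc["mRNA"] == 2 * cfg.n_genes
    assert vc["lnc_i"] == cfg.n_lnc_i
    assert vc["lnc_x"] == cfg.n_lnc_x
    assert vc["lnc_u_pair"] == 2 * (cfg.n_homolog_pairs + cfg.n_shuffled_pairs)
    n_plain = cfg.n_lnc_u - 2 * (cfg.n_homolog_pairs + cfg.n_shuffled_pairs)
    assert vc["lnc_u"] == n_plain
    for decoy in ("length", "proximity", "lowexpr", "coding", "est"):
        assert vc[f"decoy_{decoy}"] == 5
    assert len(genome.assembled) >= 200


def test_truth_class_codes_by_type(genome):
    truth = genome.truth.set_index("feature_id")
    assert (truth.loc[truth.feature_type == "lnc_i", "true_class_code"] == "i").all()
    assert (truth.loc[truth.feature_type == "lnc_x", "true_class_code"] == "x").all()
    assert (truth.loc[truth.feature_type == "lnc_u", "true_class_code"] == "u").all()
    passing = truth[truth.fail_rule == ""]
    assert set(passing.feature_type) <= {"lnc_u", "lnc_u_pair"}


def test_planted_pairs_are_mutual_and_typed(genome):
    truth = genome.truth.set_index("feature_id")
    paired = truth[truth.homolog_partner != ""]
    assert len(paired) == 2 * (genome.config.n_homolog_pairs + genome.config.n_shuffled_pairs)
    for fid, row in paired.iterrows():
        assert truth.loc[row.homolog_partner, "homolog_partner"] == fid
        assert row.syntenic_truth in {"True", "False"}
    n_syn = (paired.syntenic_truth == "True").sum()
    assert n_syn == 2 * genome.config.n_homolog_pairs


def test_gc_contrast_between_coding_and_noncoding(genome):
    truth = genome.truth.set_index("feature_id")
    seqs = {t.id: t.sequence for t in genome.assembled}
    gc_mrna = np.mean([gc_content(seqs[f]) for f in truth.index[truth.feature_type == "mRNA"]])
    gc_lnc = np.mean([gc_content(seqs[f]) for f in truth.index[truth.feature_type == "lnc_u"]])
    assert gc_mrna > gc_lnc


def test_sequences_match_genome_coordinates(genome):
    for t in genome.assembled[:30]:
        expected = "".join(genome.genome[t.chromosome][s:e] for s, e in t.exons)
        assert t.sequence == expected


def test_est_support_covers_everything_but_est_decoys(genome):
    truth = genome.truth.set_index("feature_id")
    tmap = {t.id: t for t in genome.assembled}

    def supported(fid):
        t = tmap[fid]
        ivs = genome.est_support.get(t.chromosome, [])
        return any(s < e2 and s2 < e for s2, e2 in t.exons for s, e in ivs)

    for fid in truth.index[truth.feature_type == "decoy_est"]:
        assert not supported(fid)
    for fid in truth.index[truth.fail_rule == ""]:
        assert supported(fid)


def test_generate_counts_planted_de_shift(genome, counts):
    truth = genome.truth.set_index("feature_id")
    infested = counts.design.timepoint_h > 0
    vals = counts.values
    de_up = truth.index[(truth.true_de) & (truth.true_log2fc > 0)]
    for fid in de_up[:5]:
        m_inf = vals.loc[fid, infested.to_numpy()].mean()
        m_ctl = vals.loc[fid, (~infested).to_numpy()].mean()
        assert m_inf > 2 * m_ctl  # planted 2^3 shift, generous margin


def test_generate_counts_deterministic(genome):
    c1 = generate_counts(genome)
    c2 = generate_counts(genome)
    assert c1.values.equals(c2.values)


def test_generate_null_counts_shape_and_design():
    m = generate_null_counts(50, 4, 0.1, seed=9)
    assert m.values.shape == (50, 8)
    assert m.samples_where(group="t") == [f"t_r{i}" for i in range(4)]


def test_genome_deterministic_and_seed_sensitive(default_config):
    g1 = generate_genome(default_config)
    g2 = generate_genome(SimulationConfig(seed=1))
    assert g1.genome == g2.genome
    assert g1.truth.equals(g2.truth)
    g3 = generate_genome(SimulationConfig(seed=2))
    assert g1.genome != g3.genome
    assert config_hash(default_config) == config_hash(SimulationConfig(seed=1))
    assert config_hash(default_config) != config_hash(SimulationConfig(seed=2))


def test_make_amplicon_has_unique_site():
    from lincforge.editing import locate_guide

    ref, guide = make_amplicon(seed=3)
    site = locate_guide(ref, guide)  # would raise if not unique
    assert len(guide) == 20
    assert ref[site.pam_start + 1 : site.pam_start + 3] == "GG"


def test_write_outputs_are_text(tmp_path, genome):
    genome.write(tmp_path)
    for f in ("genome.fa", "reference.gtf", "assembled.gtf", "truth.tsv",
              "est_support.bed", "annotation.tsv"):
        assert (tmp_path / f).exists()
        (tmp_path / f).read_text()  # decodable as text
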