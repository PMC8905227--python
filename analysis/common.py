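"""Shared inputs for the numbered analysis scripts.

Every script is standalone: it rebuilds the deterministic synthetic cohort
from SEED via the library, runs one stage, and writes tables under
results/<NN>_<stage>/.  Regeneration takes a few seconds and guarantees the
scripts agree without passing files between them.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from lincforge import classify as mclassify
from lincforge import coding as mcoding
from lincforge import de as mde
from lincforge.models import FilterParams
from lincforge.synthetic import SimulationConfig, generate_counts, generate_genome

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d


def load_cohort():
    genome = generate_genome(SimulationConfig(seed=SEED))
    counts = generate_counts(genome)
    return genome, counts


def identify_lncrnas(genome, counts):
    """Classify -> filter -> coding-potential; returns the pieces each script needs."""
    assignments, _ = mclassify.assign_class_codes(genome.assembled, genome.reference)
    fpkm = mde.counts_to_fpkm(counts)
    survivors, ledger = mclassify.filter_candidates(
        assignments, genome.assembled, fpkm, FilterParams(require_est_support=True),
        genome.est_support
    )
    rng = np.random.default_rng(SEED + 7)
    tmap = {t.id: t for t in genome.assembled}
    coding_train = [t.sequence for t in genome.assembled if t.id.endswith(".t1")]
    shuffled = []
    for s in coding_train:
        arr = np.array(list(s))
        rng.shuffle(arr)
        shuffled.append("".join(arr))
    model = mcoding.train_hexamer_model(coding_train, shuffled)
    scores = [mcoding.score_coding(tmap[t].sequence, model, transcript_id=t) for t in survivors]
    lnc_ids = sorted(s.transcript_id for s in scores if s.label == "noncoding")
    return assignments, fpkm, survivors, ledger, scores, lnc_ids
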