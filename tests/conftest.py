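import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ighscribe.annotate import AnnotatorConfig, annotate_locus
from ighscribe.repertoire import classify_repertoire
from ighscribe.simulate import (
    LocusSpec,
    RepertoireSpec,
    generate_locus_pair,
    generate_repertoire,
)

#: acceptance-style category mixture used by the shared big repertoire
E2E_MIXTURE = (
    ("canonical", 0.60),
    ("chimeric_mu1_delta", 0.25),
    ("noncanonical_delta", 0.05),
    ("trans_locus", 0.10),
)


@pytest.fixture(scope="session")
def locus_pair():
    """Default synthetic locus pair (18 families, 25 D, 20 JH)."""
    return generate_locus_pair(LocusSpec(seed=1))


@pytest.fixture(scope="session")
def annotation(locus_pair):
    """Annotation of both loci under the synthetic-study config."""
    out = {}
    for tag, record in locus_pair.records.items():
        config = AnnotatorConfig(ch_min_exon_identity=0.8, locus_tag=tag)
        out[tag] = annotate_locus(
            record, config, ch_references=locus_pair.ch_references
        )
    return out


@pytest.fixture(scope="session")
def big_repertoire(locus_pair):
    """2,000 error-free reads at the 0.60/0.25/0.05/0.10 mixture."""
    spec = RepertoireSpec(seed=7, n_reads=2000, category_mixture=E2E_MIXTURE)
    reads, truth = generate_repertoire(locus_pair.db, spec)
    return reads, truth, spec


@pytest.fixture(scope="session")
def big_classification(locus_pair, big_repertoire):
    reads, truth, _spec = big_repertoire
    calls, duplicates = classify_repertoire(reads, locus_pair.db)
    return calls, duplicates, truth
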