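"""Shared fixtures: toy studies, GenBank text, low-dimensional datasets."""

import numpy as np
import pytest

from phoskan.toydata import ToyStudySpec, featurize_study, generate_toy_study
from phoskan.train import WindowDataset


@pytest.fixture(scope="session")
def small_study():
    """A 12-protein toy study with the default planted signal."""
    return generate_toy_study(ToyStudySpec(n_proteins=12, seed=3))


@pytest.fixture(scope="session")
def small_dataset(small_study):
    return featurize_study(small_study)


def make_lowdim_dataset(n=300, embed_dim=32, window=9, effect=4.0,
                        n_signal_coords=6, seed=0, signal_rows=(0, 1),
                        n_proteins=20, prevalence=0.5):
    """Directly constructed windows with a planted flank-row signal.

    Positives carry ``effect`` added on the first ``n_signal_coords``
    embedding coordinates of the designated window rows; the center row
    is untouched, so the signal is only visible to window-aware models.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, window, embed_dim)).astype(np.float32)
    y = (rng.random(n) < prevalence).astype(int)
    for i in np.flatnonzero(y):
        for r in signal_rows:
            X[i, r, :n_signal_coords] += effect
    pids = [f"G{rng.integers(n_proteins):03d}" for _ in range(n)]
    return WindowDataset(X, y, pids)


@pytest.fixture()
def lowdim_dataset():
    return make_lowdim_dataset()


TOY_GENBANK_ONE_CDS = """\
LOCUS       TESTREC1                21 bp    DNA     linear   UNA 01-JAN-2000
DEFINITION  toy record with one CDS.
ACCESSION   TESTREC1
VERSION     TESTREC1
KEYWORDS    .
SOURCE      synthetic
  ORGANISM  synthetic
FEATURES             Location/Qualifiers
     CDS             7..15
                     /translation="MS"
ORIGIN
        1 acgtac atgtcataa gtacgt
//
"""

TOY_GENBANK_JOIN = """\
LOCUS       TESTREC2                24 bp    DNA     linear   UNA 01-JAN-2000
DEFINITION  toy record with a spliced CDS.
ACCESSION   TESTREC2
VERSION     TESTREC2
KEYWORDS    .
SOURCE      synthetic
  ORGANISM  synthetic
FEATURES             Location/Qualifiers
     CDS             join(3..8,15..20)
                     /translation="MSTG"
ORIGIN
        1 ccatgtcagg ttttacgggt cccc
//
"""

TOY_GENBANK_TWO_CDS = """\
LOCUS       TESTREC3                30 bp    DNA     linear   UNA 01-JAN-2000
DEFINITION  toy record with two CDS features.
ACCESSION   TESTREC3
VERSION     TESTREC3
KEYWORDS    .
SOURCE      synthetic
  ORGANISM  synthetic
FEATURES             Location/Qualifiers
     CDS             1..9
                     /translation="MS"
     CDS             10..18
                     /translation="MT"
ORIGIN
        1 atgtcataaa tgacttgacc cccccccccc
//
"""

TOY_GENBANK_NO_CDS = """\
LOCUS       TESTREC4                12 bp    DNA     linear   UNA 01-JAN-2000
DEFINITION  toy record without CDS.
ACCESSION   TESTREC4
VERSION     TESTREC4
KEYWORDS    .
SOURCE      synthetic
  ORGANISM  synthetic
FEATURES             Location/Qualifiers
     gene            1..12
ORIGIN
        1 acgtacgtac gt
//
"""
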