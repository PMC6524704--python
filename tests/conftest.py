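"""Shared fixtures: published reference peptides and small PSM tables."""

import pandas as pd
import pytest

# Published reference peptides: (profile, sequence, 9-digit class code).
# The last row is the worked class-assignment example.
REFERENCE_BARCODES = [
    ("decreasing", "GTWQRPH", "112233133"),
    ("decreasing", "KDIPVPKPK", "123233213"),
    ("decreasing", "GFGRIGR", "131133131"),
    ("decreasing", "RDEDKSKWMGK", "212333321"),
    ("decreasing", "KYDSTHGRYAGE", "221223331"),
    ("increasing", "PVGNPEGPEKPN", "222212313"),
    ("increasing", "GNPIDGKGPID", "222212313"),
    ("increasing", "QERDPANLPWGSSN", "322212323"),
    ("increasing", "QERDPANLPWGSS", "322212323"),
    ("fluctuating", "YFHEDDKF", "123213331"),
    ("fluctuating", "SSKTNPKRDWF", "223233232"),
    ("fluctuating", "GKKLEDHPKF", "223233322"),
    ("constant", "IDAPGHRDF", "122213322"),
    ("constant", "EKNVPLYKH", "123233222"),
    ("constant", "YDSTHGRYAGE", "221213331"),
    ("constant", "PLVGGHEGAGV", "231112212"),
    ("constant", "PLVGGHEGAG", "231112212"),
    ("worked_example", "KGSIDEQHPRYGG", "321223322"),
]


@pytest.fixture(scope="session")
def reference_barcodes():
    return REFERENCE_BARCODES


def make_psm(rows):
    """Build an observation table from (sequence, replicate, t, spectra)."""
    return pd.DataFrame(
        rows, columns=["sequence", "replicate", "timepoint_h", "spectra"]
    )


@pytest.fixture
def small_psm():
    """Two peptides, 2 replicates x 2 timepoints."""
    return make_psm(
        [
            ("PEPTIDE", 1, 0.0, 3),
            ("PEPTIDE", 1, 3.0, 1),
            ("PEPTIDE", 2, 0.0, 2),
            ("PEPTIDE", 2, 3.0, 2),
            ("GTWQRPH", 1, 0.0, 8),
            ("GTWQRPH", 2, 3.0, 4),
        ]
    )
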