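import numpy as np
import pytest

from fishhet.core_io import CaseCellSet, NucleusRecord


def make_cells(counts, case_id="T", source="CD", filtered=False, with_xy=True, rng=None):
    """Build a CaseCellSet from a list of (her2, cep17) pairs."""
    if rng is None:
        rng = np.random.default_rng(0)
    nuclei = []
    for i, (h, c) in enumerate(counts):
        x, y = (float(rng.uniform(0, 800)), float(rng.uniform(0, 600))) if with_xy else (None, None)
        nuclei.append(
            NucleusRecord(
                case_id=case_id, nucleus_id=f"{case_id}-{i}", source=source,
                her2=int(h), cep17=int(c), x=x, y=y,
            )
        )
    return CaseCellSet(case_id=case_id, source=source, nuclei=nuclei, filtered=filtered)


@pytest.fixture
def toy_cells():
    """Ten hand-enumerable nuclei used as the case-summary oracle fixture."""
    counts = [(2, 2), (3, 2), (4, 2), (6, 2), (12, 3), (8, 2), (2, 3), (5, 2), (7, 3), (3, 3)]
    return make_cells(counts, filtered=True)
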