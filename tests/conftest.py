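import numpy as np
import pandas as pd
import pytest

from bcstarprom.association import AssociationTable
from bcstarprom.library_design import (
    CANONICAL_BARCODE_PATTERN,
    assemble_construct,
    default_template,
    generate_promoter_insert,
    sample_barcodes,
)


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def small_library(template):
    """Thirty assembled constructs with distinct promoters and barcodes."""
    rng = np.random.default_rng(11)
    barcodes = sample_barcodes(CANONICAL_BARCODE_PATTERN, 30, rng)
    constructs = []
    for i, bc in enumerate(barcodes):
        prom = generate_promoter_insert(6, rng, promoter_id=f"P{i:03d}")
        constructs.append(assemble_construct(prom, bc, template, library_id=f"L{i:03d}"))
    return constructs


@pytest.fixture(scope="session")
def truth_assoc(small_library):
    table = pd.DataFrame(
        {
            "barcode": [c.barcode for c in small_library],
            "promoter_id": [c.promoter.promoter_id for c in small_library],
            "read_support": 99,
        }
    )
    return AssociationTable(table=table)
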