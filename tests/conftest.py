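import pytest

from poresift.classification import Lineage, LineageMap
from poresift.io_readuntil import CategorizedRead, Category, ReadRecord
from poresift.synthetic_data import TAXA


@pytest.fixture(scope="session")
def lineage_map() -> LineageMap:
    lm = LineageMap()
    for t in TAXA.values():
        lm[t.taxid] = Lineage(t.taxid, t.superkingdom, t.genus, t.species)
    return lm


def make_read(read_id: str, length: int = 1000, sequence: str | None = None) -> ReadRecord:
    if sequence is None:
        sequence = "A" * length
    return ReadRecord(read_id=read_id, length_bp=len(sequence), sequence=sequence,
                      quality="I" * len(sequence))


def make_categorized(
    read_id: str,
    category: Category,
    length: int = 1000,
    bp_to_decision: int | None = None,
) -> CategorizedRead:
    return CategorizedRead(
        read=make_read(read_id, length), category=category,
        bp_to_decision=bp_to_decision,
    )
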