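import pytest

from akicomorbid import PatientRecord, TransactionSet


def make_transactions(itemsets):
    """Build a TransactionSet from a list (or dict) of item iterables."""
    if isinstance(itemsets, dict):
        return TransactionSet(items={k: frozenset(v) for k, v in itemsets.items()})
    return TransactionSet(
        items={f"T{i:04d}": frozenset(s) for i, s in enumerate(itemsets)}
    )


def make_patient(pid="P1", scr=(), uo=(), weight=80.0, codes=()):
    return PatientRecord(
        id=pid,
        weight_kg=weight,
        scr_series=list(scr),
        uo_series=list(uo),
        codes=[(10, c) if isinstance(c, str) else c for c in codes],
    )


@pytest.fixture
def worked_pair_transactions():
    """10 patients; item A in patients 1-4, item B in patients 3-7."""
    sets = []
    for i in range(1, 11):
        items = set()
        if 1 <= i <= 4:
            items.add("A00")
        if 3 <= i <= 7:
            items.add("B00")
        items.add("C00")  # filler so every transaction is non-empty
        sets.append(items)
    return make_transactions(sets)
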