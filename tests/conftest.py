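import numpy as np
import pytest

from tecapture.domain_screen import (
    CATEGORY_MULTICOPY,
    CATEGORY_OTHER,
    CATEGORY_TE_VIRAL,
    DomainAnnotation,
    DomainSet,
    ProteinRecord,
)

MULTICOPY_POOL = ["IPR001810", "IPR011333", "IPR036770"]
TE_POOL = ["IPR041426", "IPR041588", "IPR000477"]
OTHER_POOL = [f"IPR9{i:05d}" for i in range(10)]


@pytest.fixture
def domain_sets() -> tuple[DomainSet, DomainSet]:
    return (
        DomainSet(CATEGORY_MULTICOPY, set(MULTICOPY_POOL)),
        DomainSet(CATEGORY_TE_VIRAL, set(TE_POOL)),
    )


def random_protein_records(rng: np.random.Generator, n: int) -> list[ProteinRecord]:
    """Random proteins with 0-4 domains drawn across all three categories."""
    pool = (
        [(a, CATEGORY_MULTICOPY) for a in MULTICOPY_POOL]
        + [(a, CATEGORY_TE_VIRAL) for a in TE_POOL]
        + [(a, CATEGORY_OTHER) for a in OTHER_POOL]
    )
    records = []
    for i in range(n):
        length = int(rng.integers(100, 1000))
        domains = []
        for _ in range(int(rng.integers(0, 5))):
            acc, cat = pool[int(rng.integers(len(pool)))]
            start = int(rng.integers(1, length - 10))
            end = int(rng.integers(start, min(length, start + 80) + 1))
            domains.append(DomainAnnotation(acc, start, end, cat))
        records.append(
            ProteinRecord(
                protein_id=f"P{i:05d}",
                taxon_id=f"tax{int(rng.integers(5))}",
                length=length,
                domains=domains,
            )
        )
    return records
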