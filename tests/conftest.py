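import numpy as np
import pytest

from corescan import (
    Pwm,
    SequenceRecord,
    load_library,
    pwm_from_consensus,
    score_window,
    tss_relative,
)
from corescan.scanner import MotifHit, reverse_complement


@pytest.fixture(scope="session")
def default_library():
    return load_library()


@pytest.fixture()
def two_col_pwm():
    """2-column PWM with distinct, hand-checkable probabilities."""
    probs = np.array(
        [
            [0.5, 0.1],  # A
            [0.25, 0.2],  # C
            [0.125, 0.3],  # G
            [0.125, 0.4],  # T
        ]
    )
    return Pwm(name="toy2", probs=probs, anchor_offset=0, cutoff=-100.0)


def random_pwm(rng: np.random.Generator, name: str, length: int) -> Pwm:
    probs = rng.dirichlet(np.ones(4), size=length).T
    return Pwm(
        name=name,
        probs=probs,
        anchor_offset=int(rng.integers(0, length)),
        cutoff=float(-np.inf),
    )


def random_records(rng: np.random.Generator, n: int, max_len: int, tss=None) -> list:
    records = []
    min_len = max(10, tss or 1)
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(list("ACGTN"), size=length, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        records.append(
            SequenceRecord(
                id=f"r{i:03d}",
                sequence=seq,
                tss_index=tss or int(rng.integers(1, length + 1)),
            )
        )
    return records


def naive_scan(records, matrices, strands="both"):
    """Reference scanner: an explicit double loop over every window and strand.

    Deliberately independent of the vectorized implementation — windows are
    sliced as strings and scored one by one with score_window.
    """
    hits = []
    for rec in records:
        n = len(rec.sequence)
        for sm in matrices:
            L = sm.length
            if n < L:
                continue
            for s in range(1, n - L + 2):  # 1-based window start
                window = rec.sequence[s - 1 : s - 1 + L]
                score = score_window(sm, window)
                if score >= sm.cutoff:
                    hits.append(
                        MotifHit(
                            seq_id=rec.id,
                            element=sm.name,
                            strand="+",
                            start_tss_rel=tss_relative(s, rec.tss_index),
                            anchor_tss_rel=tss_relative(s + sm.anchor_offset, rec.tss_index),
                            score=score,
                            length=L,
                        )
                    )
                if strands == "both":
                    score = score_window(sm, reverse_complement(window))
                    if score >= sm.cutoff:
                        five_prime = s + L - 1
                        hits.append(
                            MotifHit(
                                seq_id=rec.id,
                                element=sm.name,
                                strand="-",
                                start_tss_rel=tss_relative(five_prime, rec.tss_index),
                                anchor_tss_rel=tss_relative(
                                    five_prime - sm.anchor_offset, rec.tss_index
                                ),
                                score=score,
                                length=L,
                            )
                        )
    return hits


def hit_key(h: MotifHit, ndigits: int = 9):
    return (h.seq_id, h.element, h.strand, h.start_tss_rel, h.anchor_tss_rel, round(h.score, ndigits))
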