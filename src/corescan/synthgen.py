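"""Synthetic promoter generator with motifs planted at controlled positions.

Generates fixed-width promoter windows whose background bases are drawn
i.i.d. from a GC-defined background model, with element instances planted
at specified TSS-relative positions. This emulates the positional structure
of real promoter windows around accurately mapped TSSs — an initiator at
-2, a DPE at +28 on the initiator-A+1 axis, a TATA box near -30 — without
modelling genomic realism (repeats, isochores, dinucleotide bias).

Each plant is controlled by a :class:`PlantSpec`: target position, per-
sequence plant probability, a discrete symmetric positional jitter, and a
choice between planting the consensus instance (default, exact ground
truth) or an instance sampled column-wise from the PWM (realistic motif
variability). Plants are applied in spec order on the plus strand; a later
plant may overwrite part of an earlier one, in which case the earlier
ground-truth row is marked overlapped. Ground truth is emitted as a
separate table so the FASTA stays standard-format.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motif_model import ALPHABET, MotifModelError, Pwm, background_from_gc
from .scanner import SequenceRecord, tss_absolute

__all__ = ["PlantSpec", "generate"]

TRUTH_COLUMNS = [
    "seq_id",
    "element",
    "axis",
    "position",
    "start_abs",
    "sequence",
    "overlapped",
]


@dataclass(frozen=True)
class PlantSpec:
    """One planting instruction.

    Parameters
    ----------
    element
        Name of a PWM available to the generator.
    position
        Target start position of the instance. On the TSS axis
        (``anchor is None``) this is a zero-free TSS-relative coordinate;
        with ``anchor`` set it is a position on that element's A+1 axis
        (A+1 = +1), so a DPE planted at +28 starts 27 bases downstream of
        the planted initiator's A+1.
    probability
        Per-sequence plant probability in [0, 1].
    jitter_sd
        Standard deviation (in positions) of a discrete symmetric jitter
        added to the target (a rounded normal draw); 0 plants exactly.
    sample_from_pwm
        If True, draw the instance column-wise from the PWM probabilities;
        if False (default) plant the consensus.
    anchor
        Name of an earlier spec's element whose planted A+1 defines the
        axis; if that element was not planted in a given sequence, the
        dependent plant is skipped there.
    """

    element: str
    position: int
    probability: float = 1.0
    jitter_sd: float = 0.0
    sample_from_pwm: bool = False
    anchor: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise MotifModelError(f"plant probability {self.probability} outside [0, 1]")
        if self.jitter_sd < 0:
            raise MotifModelError("jitter sd must be >= 0")
        if self.position == 0:
            raise MotifModelError("zero-free axes have no position 0")


def _instance(pwm: Pwm, rng: np.random.Generator, sample: bool) -> str:
    if not sample:
        return pwm.consensus
    idx = [rng.choice(4, p=pwm.probs[:, j]) for j in range(pwm.length)]
    return "".join(ALPHABET[i] for i in idx)


def _skip_zero(d: int) -> int:
    return d + 1 if d >= 0 else d


def generate(
    n: int,
    width: int,
    tss_index: int,
    gc: float,
    plants: Sequence[PlantSpec],
    pwms: Mapping[str, Pwm],
    seed: int,
    id_prefix: str = "synth",
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate ``n`` promoter windows plus a ground-truth table.

    Background bases are i.i.d. from ``background_from_gc(gc)``. The same
    seed yields byte-identical output. The ground-truth frame has columns
    (seq_id, element, axis, position, start_abs, sequence, overlapped);
    ``position`` is the start actually planted after jitter, on the spec's
    axis. A plant whose instance would extend outside the sequence is
    skipped and does not appear in the truth table.
    """
    if n < 1 or width < 1 or not 1 <= tss_index <= width:
        raise MotifModelError("need n >= 1 and 1 <= tss_index <= width")
    longest = max((pwms[s.element].length for s in plants), default=1)
    if width < longest:
        raise MotifModelError(f"width {width} shorter than longest planted motif ({longest})")
    for s in plants:
        if s.element not in pwms:
            raise MotifModelError(f"no PWM for planted element {s.element!r}")
        if s.anchor is not None and s.anchor not in {p.element for p in plants}:
            raise MotifModelError(
                f"plant {s.element!r} anchored to {s.anchor!r}, which is not planted"
            )
    rng = np.random.default_rng(seed)
    bg = background_from_gc(gc).vector
    records: list[SequenceRecord] = []
    truth_rows: list[dict] = []
    pad = len(str(n))
    for i in range(n):
        seq_id = f"{id_prefix}{i + 1:0{pad}d}"
        seq = rng.choice(4, size=width, p=bg)
        chars = list("".join(ALPHABET[b] for b in seq))
        planted_a1: dict[str, int] = {}  # element -> absolute A+1 column
        placed: list[tuple[int, int, int]] = []  # (start0, end0, truth row index)
        for spec in plants:
            if rng.random() >= spec.probability:
                continue  # random() < 1, so probability 1.0 always plants
            pwm = pwms[spec.element]
            jitter = int(round(rng.normal(0.0, spec.jitter_sd))) if spec.jitter_sd > 0 else 0
            if spec.anchor is None:
                base_abs = tss_absolute(spec.position, tss_index)
            else:
                if spec.anchor not in planted_a1:
                    continue
                d = spec.position - 1 if spec.position > 0 else spec.position
                base_abs = planted_a1[spec.anchor] + d
            start_abs = base_abs + jitter
            start0 = start_abs - 1
            end0 = start0 + pwm.length
            if start0 < 0 or end0 > width:
                continue  # would extend outside the window; skipped
            inst = _instance(pwm, rng, spec.sample_from_pwm)
            chars[start0:end0] = list(inst)
            for ps, pe, ridx in placed:
                if ps < end0 and start0 < pe:
                    truth_rows[ridx]["overlapped"] = True
            if spec.anchor is None:
                pos_label = _skip_zero(start_abs - tss_index)
                axis = "tss"
            else:
                a1 = planted_a1[spec.anchor]
                pos_label = _skip_zero(start_abs - a1)
                axis = f"anchor:{spec.anchor}"
            planted_a1[spec.element] = start_abs + pwm.anchor_offset
            truth_rows.append(
                {
                    "seq_id": seq_id,
                    "element": spec.element,
                    "axis": axis,
                    "position": pos_label,
                    "start_abs": start_abs,
                    "sequence": inst,
                    "overlapped": False,
                }
            )
            placed.append((start0, end0, len(truth_rows) - 1))
        records.append(SequenceRecord(id=seq_id, sequence="".join(chars), tss_index=tss_index))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return records, truth
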