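"""Curated core promoter element set, user motifs, and composite spacing rules.

The bundled library covers the classical metazoan core promoter elements
(TATA box, human Inr, Drosophila Inr, BBCA+1BW initiator, DPE, MTE, BREu,
BREd, TCT, dTCT, Bridge) plus the pausing-associated motifs (pause button,
Ohler Motif 1, GAGA factor binding site). The shipped matrices are synthetic
reconstructions built from the published consensus of each element — the
experimentally derived matrices of the original tool are an external
download and are not reproduced here — so the library is suitable for method
development and simulation, while production use on real promoters should
import the user's matrices of choice via :meth:`Library.add_user_motif`.

Composite rules express the dependency of downstream elements (DPE, MTE,
Bridge) on an initiator: the dependent element is only called when an
initiator hit exists on the same sequence and strand with the dependent
start inside an allowed spacing window measured from the initiator's A+1
base (the A+1 is position +1 of the spacing axis, which has no 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .motif_model import (
    MotifModelError,
    Pwm,
    read_pwm,
    write_pwm,
)

__all__ = [
    "CATEGORIES",
    "ElementDefinition",
    "CompositeRule",
    "Library",
    "load_library",
    "write_library",
]

CATEGORIES = ("initiator", "upstream", "downstream", "pausing", "user")

_RULES_FILE = "rules.yaml"


@dataclass(frozen=True)
class ElementDefinition:
    """A library entry: PWM plus biological metadata.

    ``default_search_window`` is the TSS-relative interval where the element
    is typically found; it is descriptive metadata for reports and never a
    hard filter on hits.
    """

    name: str
    pwm: Pwm
    category: str = "user"
    default_search_window: tuple[int, int] | None = None
    citation: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise MotifModelError(
                f"element {self.name!r}: unknown category {self.category!r}"
            )
        if self.name != self.pwm.name:
            raise MotifModelError(
                f"element name {self.name!r} does not match PWM name {self.pwm.name!r}"
            )


@dataclass(frozen=True)
class CompositeRule:
    """Dependent element called only near an initiator anchor.

    ``spacing_window`` is an inclusive interval of allowed positions of the
    dependent element's start on the anchor-A+1 axis (anchor A+1 base = +1,
    no position 0); e.g. the classical DPE sits at +28..+33 from the A+1.
    """

    dependent: str
    anchor: str
    spacing_window: tuple[int, int]

    def __post_init__(self) -> None:
        lo, hi = self.spacing_window
        if lo > hi:
            raise MotifModelError(
                f"rule {self.dependent}->{self.anchor}: empty spacing window {lo}..{hi}"
            )
        object.__setattr__(self, "spacing_window", (int(lo), int(hi)))

    @property
    def midpoint(self) -> float:
        lo, hi = self.spacing_window
        return (lo + hi) / 2.0


class Library:
    """An ordered, name-unique collection of elements plus composite rules."""

    def __init__(
        self,
        elements: Iterable[ElementDefinition] = (),
        rules: Iterable[CompositeRule] = (),
    ) -> None:
        self._elements: dict[str, ElementDefinition] = {}
        for el in elements:
            if el.name in self._elements:
                raise MotifModelError(f"duplicate element name {el.name!r}")
            self._elements[el.name] = el
        self.rules: list[CompositeRule] = list(rules)
        self._check_rules()

    def _check_rules(self) -> None:
        for rule in self.rules:
            for name in (rule.dependent, rule.anchor):
                if name not in self._elements:
                    raise MotifModelError(
                        f"composite rule references unknown element {name!r}"
                    )
            if self._elements[rule.anchor].category != "initiator":
                raise MotifModelError(
                    f"composite anchor {rule.anchor!r} is not an initiator"
                )

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._elements)

    def __contains__(self, name: str) -> bool:
        return name in self._elements

    def __getitem__(self, name: str) -> ElementDefinition:
        return self._elements[name]

    def __iter__(self):
        return iter(self._elements.values())

    @property
    def names(self) -> list[str]:
        return list(self._elements)

    # -- editing ------------------------------------------------------------
    def add_user_motif(self, pwm_or_path) -> "Library":
        """Add a user-defined motif (category ``user``); returns self.

        Accepts a :class:`~corescan.motif_model.Pwm` or a path to a PWM file.
        The motif is scanned identically to built-ins. A name clash with an
        existing element is an error.
        """
        if isinstance(pwm_or_path, Pwm):
            pwm = pwm_or_path
        else:
            pwm, _ = read_pwm(pwm_or_path)
        if pwm.name in self._elements:
            raise MotifModelError(
                f"element {pwm.name!r} already exists in the library"
            )
        self._elements[pwm.name] = ElementDefinition(
            name=pwm.name, pwm=pwm, category="user"
        )
        return self

    def subset(self, names: Iterable[str]) -> "Library":
        """Library restricted to the given element names (rules kept when both
        ends survive)."""
        names = list(names)
        missing = [n for n in names if n not in self._elements]
        if missing:
            raise MotifModelError(f"unknown element(s): {', '.join(missing)}")
        keep = set(names)
        return Library(
            elements=[self._elements[n] for n in names],
            rules=[
                r for r in self.rules if r.dependent in keep and r.anchor in keep
            ],
        )

    def with_cutoffs(self, overrides: Mapping[str, float]) -> "Library":
        """Copy of the library with per-element cutoff overrides applied."""
        missing = [n for n in overrides if n not in self._elements]
        if missing:
            raise MotifModelError(f"cutoff override for unknown element(s): {missing}")
        elements = []
        for el in self:
            if el.name in overrides:
                el = replace(el, pwm=replace(el.pwm, cutoff=float(overrides[el.name])))
            elements.append(el)
        return Library(elements=elements, rules=list(self.rules))


def _parse_window(text: str) -> tuple[int, int]:
    lo, _, hi = text.partition(":")
    return int(lo), int(hi)


def _default_library_dir() -> Path:
    return Path(resources.files("corescan").joinpath("data", "synthetic_library"))


def load_library(directory=None) -> Library:
    """Load a library directory (one ``*.pwm`` file per element + rules.yaml).

    With no argument, loads the bundled synthetic consensus-derived default
    set. An empty directory yields an empty library with a warning.
    """
    directory = Path(directory) if directory is not None else _default_library_dir()
    if not directory.is_dir():
        raise MotifModelError(f"library directory not found: {directory}")
    elements: list[ElementDefinition] = []
    seen: set[str] = set()
    for path in sorted(directory.glob("*.pwm")):
        pwm, meta = read_pwm(path)
        if pwm.name in seen:
            raise MotifModelError(f"{path}: duplicate element name {pwm.name!r}")
        seen.add(pwm.name)
        window = _parse_window(meta["window"]) if "window" in meta else None
        elements.append(
            ElementDefinition(
                name=pwm.name,
                pwm=pwm,
                category=meta.get("category", "user"),
                default_search_window=window,
                citation=meta.get("citation", ""),
            )
        )
    if not elements:
        warnings.warn(f"library directory {directory} contains no PWM files", stacklevel=2)
    rules: list[CompositeRule] = []
    rules_path = directory / _RULES_FILE
    if rules_path.exists():
        with open(rules_path) as fh:
            cfg = yaml.safe_load(fh) or {}
        for entry in cfg.get("composite_rules", []):
            rules.append(
                CompositeRule(
                    dependent=entry["dependent"],
                    anchor=entry["anchor"],
                    spacing_window=tuple(entry["spacing_window"]),
                )
            )
    return Library(elements=elements, rules=rules)


def write_library(library: Library, directory) -> None:
    """Write a library as a directory loadable by :func:`load_library`.

    Round-trips bit-exactly at the PWM file precision (6 decimal digits).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for el in library:
        meta: dict[str, str] = {"category": el.category}
        if el.default_search_window is not None:
            lo, hi = el.default_search_window
            meta["window"] = f"{lo}:{hi}"
        if el.citation:
            meta["citation"] = el.citation
        write_pwm(el.pwm, directory / f"{el.name}.pwm", extra_meta=meta)
    if library.rules:
        payload = {
            "composite_rules": [
                {
                    "dependent": r.dependent,
                    "anchor": r.anchor,
                    "spacing_window": list(r.spacing_window),
                }
                for r in library.rules
            ]
        }
        with open(directory / _RULES_FILE, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
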