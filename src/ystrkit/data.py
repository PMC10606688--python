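"""Y-STR allele/haplotype data model, panel registry, and tab-separated IO.

A man's Y-STR profile is a *haplotype*: one :class:`LocusCall` per marker.
Single-copy markers normally yield one allele; the duplicated marker
DYS385a/b yields an unordered pair, and copy-number variants yield three or
more alleles at a locus.  Microvariant alleles carry a partial repeat and are
written with one decimal digit (``13.1`` = 13 repeats plus one extra base).

Haplotype tables are plain TSV: ``sample_id``, ``population``, then one
column per locus, with multi-allele cells joined by ``-`` (``"11-14"``).
"""

from __future__ import annotations

import csv
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import (
    AlleleParseError,
    EmptyDatasetError,
    IncompleteHaplotypeError,
    TableFormatError,
)

logger = logging.getLogger(__name__)

_ALLELE_RE = re.compile(r"^(\d+)(?:\.(\d))?$")

#: column headers reserved for metadata in haplotype tables
RESERVED_COLUMNS = ("sample_id", "population")

#: default cell separator for multi-allele locus calls
MULTI_ALLELE_SEP = "-"


@dataclass(frozen=True, order=True)
class Allele:
    """A repeat-count allele, optionally with a partial-repeat microvariant.

    ``Allele(13, 1)`` renders as ``"13.1"``: 13 full repeats plus 1 extra
    base.  Ordering by ``(repeats, partial)`` coincides with numeric order
    because a partial repeat is always shorter than one repeat unit.
    """

    repeats: int
    partial: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 0:
            raise AlleleParseError(f"negative repeat count: {self.repeats}")
        if not 0 <= self.partial < 4:
            raise AlleleParseError(
                f"partial repeat must be 0-3 bases, got {self.partial}"
            )

    @property
    def value(self) -> float:
        """Numeric face value used where a distance requires one number."""
        return self.repeats + self.partial / 10.0

    @property
    def label(self) -> str:
        return f"{self.repeats}.{self.partial}" if self.partial else str(self.repeats)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label

    @classmethod
    def parse(cls, text: str) -> "Allele":
        m = _ALLELE_RE.match(text.strip())
        if m is None:
            raise AlleleParseError(f"not a valid allele label: {text!r}")
        return cls(int(m.group(1)), int(m.group(2) or 0))


def parse_allele(text: str) -> Allele:
    """Parse an allele label such as ``"14"`` or ``"13.1"``."""
    return Allele.parse(text)


@dataclass(frozen=True)
class LocusCall:
    """The observed allele multiset at one locus for one individual.

    Alleles are stored sorted ascending so that entry order never affects
    equality; ``"14-11"`` and ``"11-14"`` denote the same call.
    """

    locus: str
    alleles: tuple[Allele, ...]

    def __post_init__(self) -> None:
        if not self.alleles:
            raise AlleleParseError(f"empty allele set at locus {self.locus!r}")
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @property
    def size(self) -> int:
        return len(self.alleles)

    @property
    def label(self) -> str:
        """Canonical cell text: sorted allele labels joined by ``-``."""
        return MULTI_ALLELE_SEP.join(a.label for a in self.alleles)

    def is_cnv(self, expected_copies: int = 1) -> bool:
        """True when the call carries more alleles than the locus normally has."""
        return self.size > expected_copies

    @classmethod
    def parse(cls, locus: str, text: str, sep: str = MULTI_ALLELE_SEP) -> "LocusCall":
        parts = [p for p in text.strip().split(sep) if p != ""]
        if not parts:
            raise AlleleParseError(f"empty cell at locus {locus!r}")
        return cls(locus, tuple(Allele.parse(p) for p in parts))


@dataclass(frozen=True)
class PanelDef:
    """A named ordered subset of loci."""

    name: str
    loci: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "loci", tuple(self.loci))
        if len(set(self.loci)) != len(self.loci):
            raise TableFormatError(f"panel {self.name!r} lists duplicate loci")

    def __contains__(self, locus: str) -> bool:
        return locus in self.loci

    def __len__(self) -> int:
        return len(self.loci)

    def is_subset_of(self, other: "PanelDef") -> bool:
        return set(self.loci) <= set(other.loci)


def _load_registry_dict(doc: Mapping) -> tuple[dict[str, PanelDef], dict[str, int]]:
    panels: dict[str, PanelDef] = {}
    for entry in doc.get("panels", []):
        name = entry["name"]
        if "extends" in entry:
            base = panels[entry["extends"]]
            loci = base.loci + tuple(entry["add"])
        else:
            loci = tuple(entry["loci"])
        panels[name] = PanelDef(name, loci)
    multi = {str(k): int(v) for k, v in (doc.get("multi_copy") or {}).items()}
    return panels, multi


def load_panel_registry(path: str | Path) -> dict[str, PanelDef]:
    """Load an alternative panel registry from a YAML file."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    panels, _ = _load_registry_dict(doc)
    return panels


_BUILTIN_DOC = yaml.safe_load(
    resources.files("ystrkit").joinpath("panels.yaml").read_text(encoding="utf-8")
)
_BUILTIN_PANELS, _MULTI_COPY = _load_registry_dict(_BUILTIN_DOC)

#: panel names ordered coarse -> fine (each a subset of the next)
PANEL_CHAIN: tuple[str, ...] = (
    "Minimal",
    "PowerPlexY12",
    "Yfiler",
    "PowerPlexY23",
    "Microreader24Y",
)


def builtin_panels() -> dict[str, PanelDef]:
    return dict(_BUILTIN_PANELS)


def get_panel(name: str) -> PanelDef:
    try:
        return _BUILTIN_PANELS[name]
    except KeyError:
        raise KeyError(
            f"unknown panel {name!r}; built-ins: {', '.join(_BUILTIN_PANELS)}"
        ) from None


def expected_copies(locus: str) -> int:
    """Number of copies a locus normally carries (2 for DYS385a/b, else 1)."""
    return _MULTI_COPY.get(locus, 1)


def known_loci() -> frozenset[str]:
    return frozenset(_BUILTIN_PANELS[PANEL_CHAIN[-1]].loci)


def canonical_locus_order(loci: Iterable[str]) -> list[str]:
    """Built-in panel order for known loci, extras appended alphabetically."""
    loci = set(loci)
    ordered = [l for l in _BUILTIN_PANELS[PANEL_CHAIN[-1]].loci if l in loci]
    ordered += sorted(loci.difference(ordered))
    return ordered


@dataclass(frozen=True)
class Haplotype:
    """Ordered locus calls for one individual."""

    sample_id: str
    calls: Mapping[str, LocusCall]
    population: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "calls", dict(self.calls))

    @property
    def loci(self) -> frozenset[str]:
        return frozenset(self.calls)

    def key(self, loci: Sequence[str] | None = None) -> str:
        """Canonical identity string over ``loci`` (default: all loci carried).

        Two haplotypes compare equal on a locus set iff their keys are equal;
        the key sorts loci and allele multisets so entry order never matters.
        """
        chosen = sorted(self.calls) if loci is None else sorted(loci)
        missing = [l for l in chosen if l not in self.calls]
        if missing:
            raise IncompleteHaplotypeError(self.sample_id, missing)
        return "|".join(f"{l}={self.calls[l].label}" for l in chosen)

    def project(self, panel: PanelDef) -> "Haplotype":
        return project_to_panel(self, panel)


def project_to_panel(h: Haplotype, panel: PanelDef) -> Haplotype:
    """Restrict a haplotype to the loci of ``panel``.

    Projection to the haplotype's own locus set is the identity; for nested
    panels p < q, projecting via q first changes nothing.
    """
    missing = [l for l in panel.loci if l not in h.calls]
    if missing:
        raise IncompleteHaplotypeError(h.sample_id, missing)
    return Haplotype(
        sample_id=h.sample_id,
        calls={l: h.calls[l] for l in panel.loci},
        population=h.population,
    )


@dataclass
class PopulationDataset:
    """A named collection of haplotypes (one per sampled individual)."""

    name: str
    haplotypes: list[Haplotype] = field(default_factory=list)

    @property
    def N(self) -> int:
        return len(self.haplotypes)

    def __len__(self) -> int:
        return self.N

    @property
    def loci(self) -> frozenset[str]:
        out: set[str] = set()
        for h in self.haplotypes:
            out |= h.loci
        return frozenset(out)

    def complete_for(self, panel: PanelDef) -> tuple[list[Haplotype], list[Haplotype]]:
        """Split haplotypes into (complete, incomplete) for a panel."""
        need = set(panel.loci)
        ok, bad = [], []
        for h in self.haplotypes:
            (ok if need <= h.loci else bad).append(h)
        return ok, bad

    def project(self, panel: PanelDef) -> "PopulationDataset":
        ok, bad = self.complete_for(panel)
        if bad:
            logger.info(
                "dataset %s: excluding %d haplotype(s) incomplete for panel %s",
                self.name, len(bad), panel.name,
            )
        return PopulationDataset(self.name, [h.project(panel) for h in ok])


def multiplicity_spectrum(
    dataset: PopulationDataset,
    panel: PanelDef | None = None,
) -> dict[int, int]:
    """Map multiplicity k -> number of distinct haplotypes seen exactly k times.

    Satisfies ``sum(k * spectrum[k]) == N`` and ``sum(spectrum.values()) == M``
    (the number of distinct haplotypes).  Haplotypes incomplete for the panel
    are excluded with a logged count.
    """
    loci = None if panel is None else panel.loci
    keys = []
    skipped = 0
    for h in dataset.haplotypes:
        try:
            keys.append(h.key(loci))
        except IncompleteHaplotypeError:
            skipped += 1
    if skipped:
        logger.info(
            "dataset %s: %d haplotype(s) incomplete for %s excluded from spectrum",
            dataset.name, skipped, panel.name if panel else "full locus set",
        )
    if not keys:
        raise EmptyDatasetError(
            f"dataset {dataset.name!r} has no complete haplotypes"
        )
    class_sizes = Counter(Counter(keys).values())
    return dict(sorted(class_sizes.items()))


def read_haplotype_table(
    path: str | Path,
    *,
    name: str | None = None,
    delimiter: str = "\t",
    multi_sep: str = MULTI_ALLELE_SEP,
    missing: str = "",
) -> PopulationDataset:
    """Read a TSV haplotype table into a :class:`PopulationDataset`.

    The header must list ``sample_id`` (and optionally ``population``)
    before the locus columns.  Cells equal to ``missing`` become absent
    locus calls; malformed cells raise :class:`TableFormatError` with
    row/column coordinates.  Locus columns outside the built-in registry
    are parsed with a warning.
    """
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise EmptyDatasetError(f"{path}: empty file") from None
        header = [c.strip() for c in header]
        if not header or header[0] != "sample_id":
            raise TableFormatError(
                f"{path}: first column must be 'sample_id', got {header[:1]}"
            )
        has_pop = len(header) > 1 and header[1] == "population"
        loci = header[2:] if has_pop else header[1:]
        unknown = [l for l in loci if l not in known_loci()]
        if unknown:
            logger.warning(
                "%s: column(s) not in the built-in locus registry: %s",
                path, ", ".join(unknown),
            )
        haplotypes: list[Haplotype] = []
        for row_num, row in enumerate(reader, start=2):
            if not row or all(c.strip() == "" for c in row):
                continue
            if len(row) != len(header):
                raise TableFormatError(
                    f"{path}: row {row_num} has {len(row)} fields, expected "
                    f"{len(header)}"
                )
            sample_id = row[0].strip()
            population = row[1].strip() if has_pop else (name or path.stem)
            calls: dict[str, LocusCall] = {}
            for locus, cell in zip(loci, row[2:] if has_pop else row[1:]):
                cell = cell.strip()
                if cell == missing:
                    continue
                try:
                    calls[locus] = LocusCall.parse(locus, cell, sep=multi_sep)
                except AlleleParseError as exc:
                    raise TableFormatError(
                        f"{path}: row {row_num}, column {locus!r}: {exc}"
                    ) from exc
            haplotypes.append(Haplotype(sample_id, calls, population))
    if not haplotypes:
        raise EmptyDatasetError(f"{path}: no data rows")
    return PopulationDataset(name or path.stem, haplotypes)


def write_haplotype_table(
    dataset: PopulationDataset,
    path: str | Path,
    *,
    loci: Sequence[str] | None = None,
    delimiter: str = "\t",
    missing: str = "",
) -> None:
    """Write a dataset as a TSV haplotype table (inverse of the reader)."""
    if loci is None:
        loci = canonical_locus_order(dataset.loci)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["sample_id", "population", *loci])
        for h in dataset.haplotypes:
            row = [h.sample_id, h.population]
            row += [h.calls[l].label if l in h.calls else missing for l in loci]
            writer.writerow(row)
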