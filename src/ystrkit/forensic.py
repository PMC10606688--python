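"""Forensic diversity statistics over haplotype multiplicity spectra.

All haplotype-level statistics are functions of the *multiplicity spectrum*
alone (how many distinct haplotypes were seen once, twice, ...):

* haplotype diversity         HD  = N (1 - sum pi^2) / (N - 1)
* haplotype match probability HMP = sum pi^2
* discrimination capacity     DC  = M / N

with pi the sample frequency of the i-th distinct haplotype, M the number of
distinct haplotypes and N the sample size.  Gene diversity (GD) is the
per-locus analogue over allele frequencies, with the same N/(N-1) correction.
"""

from __future__ import annotations

import csv
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .data import (
    LocusCall,
    PanelDef,
    PopulationDataset,
    canonical_locus_order,
    multiplicity_spectrum,
)
from .errors import EmptyDatasetError, UndefinedStatisticError, YstrError

Spectrum = Mapping[int, int]


def _check_spectrum(spectrum: Spectrum, n: int | None) -> int:
    if not spectrum:
        raise EmptyDatasetError("empty multiplicity spectrum")
    for k, c in spectrum.items():
        if k < 1 or c < 1:
            raise YstrError(f"invalid spectrum entry {k}:{c}")
    total = sum(k * c for k, c in spectrum.items())
    if n is not None and n != total:
        raise YstrError(f"spectrum sums to {total} individuals, but N={n} given")
    return total


def distinct_count(spectrum: Spectrum) -> int:
    """Number of distinct haplotypes M implied by a spectrum."""
    _check_spectrum(spectrum, None)
    return sum(spectrum.values())


def match_probability(spectrum: Spectrum, n: int | None = None) -> float:
    """HMP = sum over distinct haplotypes of (k/N)^2."""
    n = _check_spectrum(spectrum, n)
    return sum(c * (k / n) ** 2 for k, c in spectrum.items())


def haplotype_diversity(spectrum: Spectrum, n: int | None = None) -> float:
    """HD = N (1 - sum pi^2) / (N - 1); undefined for N < 2."""
    n = _check_spectrum(spectrum, n)
    if n < 2:
        raise UndefinedStatisticError("haplotype diversity requires N >= 2")
    return n * (1.0 - match_probability(spectrum, n)) / (n - 1)


def discrimination_capacity(m: int, n: int) -> float:
    """DC = M/N for M distinct haplotypes among N individuals."""
    if not 1 <= m <= n:
        raise YstrError(f"need 1 <= M <= N, got M={m}, N={n}")
    return m / n


def spectrum_percentages(spectrum: Spectrum) -> dict[int, float]:
    """Share of *distinct* haplotypes at each multiplicity, in percent.

    Values are rounded to 2 decimals and therefore sum to 100 only up to
    rounding error.
    """
    m = distinct_count(spectrum)
    return {k: round(100.0 * c / m, 2) for k, c in sorted(spectrum.items())}


@dataclass(frozen=True)
class PanelSummary:
    """One row of a multi-panel forensic summary table."""

    panel: str
    n: int
    m: int
    spectrum: dict[int, int]
    hd: float
    hmp: float
    dc: float

    @classmethod
    def from_spectrum(cls, panel: str, spectrum: Spectrum) -> "PanelSummary":
        n = _check_spectrum(spectrum, None)
        m = distinct_count(spectrum)
        return cls(
            panel=panel,
            n=n,
            m=m,
            spectrum=dict(sorted(spectrum.items())),
            hd=haplotype_diversity(spectrum, n),
            hmp=match_probability(spectrum, n),
            dc=discrimination_capacity(m, n),
        )


def panel_summary(dataset: PopulationDataset, panel: PanelDef) -> PanelSummary:
    spectrum = multiplicity_spectrum(dataset, panel)
    return PanelSummary.from_spectrum(panel.name, spectrum)


def panel_summary_table(
    dataset: PopulationDataset, panels: Sequence[PanelDef]
) -> list[PanelSummary]:
    """Forensic parameters for each panel (HD/HMP/DC/M plus the spectrum)."""
    return [panel_summary(dataset, p) for p in panels]


@dataclass(frozen=True)
class LocusFrequencyTable:
    """Allele (or genotype-pattern) counts and gene diversity at one locus.

    For multi-copy loci each distinct sorted allele multiset is one category,
    so DYS385a/b receives a single GD value.
    """

    locus: str
    counts: dict[str, int]

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[str, float]:
        n = self.n
        return {label: c / n for label, c in self.counts.items()}

    @property
    def gd(self) -> float:
        n = self.n
        if n < 2:
            raise UndefinedStatisticError("gene diversity requires N >= 2")
        sum_sq = sum((c / n) ** 2 for c in self.counts.values())
        return n * (1.0 - sum_sq) / (n - 1)


def gene_diversity(locus_calls: Iterable[LocusCall]) -> LocusFrequencyTable:
    """Build the frequency table (and GD) from the calls observed at one locus."""
    calls = list(locus_calls)
    if not calls:
        raise EmptyDatasetError("no locus calls supplied")
    locus = calls[0].locus
    if any(c.locus != locus for c in calls):
        raise YstrError("locus calls mix multiple loci")
    counts = Counter(c.label for c in calls)
    return LocusFrequencyTable(locus, dict(sorted(counts.items())))


def locus_tables(
    dataset: PopulationDataset, loci: Sequence[str] | None = None
) -> list[LocusFrequencyTable]:
    """Per-locus frequency/GD tables; individuals missing a locus are skipped."""
    if loci is None:
        loci = canonical_locus_order(dataset.loci)
    out = []
    for locus in loci:
        calls = [h.calls[locus] for h in dataset.haplotypes if locus in h.calls]
        if calls:
            out.append(gene_diversity(calls))
    return out


def format_hmp(hmp: float, sig: int = 3) -> str:
    """Scientific rendering with ``sig`` significant digits, e.g. ``1.14e-03``."""
    if hmp <= 0:
        return "0"
    exponent = math.floor(math.log10(hmp))
    mantissa = hmp / 10**exponent
    mantissa = round(mantissa, sig - 1)
    if mantissa >= 10:  # rounding carried over
        mantissa /= 10
        exponent += 1
    return f"{mantissa:.{sig - 1}f}e{exponent:+03d}"


def write_summary_tsv(summaries: Sequence[PanelSummary], path: str | Path) -> None:
    """Write a panel summary table as TSV (HD/DC to 6 decimals, HMP 3 s.f.)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["panel", "N", "M", "HD", "HMP", "DC", "spectrum"]
        )
        for s in summaries:
            spec_txt = ",".join(f"{k}:{c}" for k, c in sorted(s.spectrum.items()))
            writer.writerow(
                [s.panel, s.n, s.m, f"{s.hd:.6f}", format_hmp(s.hmp),
                 f"{s.dc:.6f}", spec_txt]
            )


def write_locus_tables_tsv(
    tables: Sequence[LocusFrequencyTable], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["locus", "category", "count", "frequency", "GD"])
        for t in tables:
            gd = f"{t.gd:.4f}"
            for label, count in t.counts.items():
                writer.writerow(
                    [t.locus, label, count, f"{count / t.n:.4f}", gd]
                )
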