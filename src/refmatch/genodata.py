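"""Core data model and text-format I/O for genotype, haplotype and posterior data.

The pipeline works with three in-memory containers:

* :class:`GenotypePanel` -- unphased diploid hard calls for one labelled
  population, stored as counted-allele doses in {0, 1, 2} (``-1`` = missing).
* :class:`HaplotypePanel` -- phased 0/1 haplotypes used as an imputation
  reference (``1`` = counted allele).
* :class:`PosteriorPanel` -- per-genotype probability triples
  ``(P0, P1, P2)`` over the counted-allele dose, as produced by imputation.

The counted allele is always ``alleleA`` -- the REF / first-listed allele of
the source file -- and every downstream frequency counts that allele, so the
sign of frequency differences is unambiguous across populations.

Supported text dialects: VCF 4.x (GT only, via cyvcf2), PLINK PED/MAP
whitespace text, Oxford HAPS-like phased tables, Oxford GEN posterior files
(five leading columns, then one ``P0 P1 P2`` triple per sample, in
counted-allele dose order) and MaCH ``mlprob`` rows (two probabilities per
genotype, ``P2`` implied as ``1 - P0 - P1``). All writers emit LF line
endings and six significant digits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

MISSING = -1

_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class PanelFormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP with its counted allele.

    ``alleleA`` is the counted allele (file REF / first-listed allele);
    ``ambiguous`` is true iff the allele pair is {A,T} or {C,G}, i.e. the
    strand of the marker cannot be verified from the alleles alone.
    """

    id: str
    chrom: str
    pos: int
    alleleA: str
    alleleB: str

    def __post_init__(self) -> None:
        if self.alleleA not in _BASES or self.alleleB not in _BASES:
            raise ValueError(
                f"marker {self.id}: alleles must be single bases, got "
                f"{self.alleleA!r}/{self.alleleB!r}"
            )
        if self.alleleA == self.alleleB:
            raise ValueError(f"marker {self.id}: alleles must differ")

    @property
    def ambiguous(self) -> bool:
        return {self.alleleA, self.alleleB} in ({"A", "T"}, {"C", "G"})

    def complemented(self) -> "Marker":
        """Same marker with both allele labels strand-complemented."""
        return Marker(self.id, self.chrom, self.pos,
                      _COMPLEMENT[self.alleleA], _COMPLEMENT[self.alleleB])

    def swapped(self) -> "Marker":
        """Same marker with counted and other allele exchanged."""
        return Marker(self.id, self.chrom, self.pos, self.alleleB, self.alleleA)


def _check_marker_order(markers: list[Marker]) -> None:
    last: dict[str, int] = {}
    for mk in markers:
        prev = last.get(mk.chrom)
        if prev is not None and mk.pos <= prev:
            raise ValueError(
                f"marker {mk.id}: position {mk.pos} not strictly increasing "
                f"on chromosome {mk.chrom}"
            )
        last[mk.chrom] = mk.pos


def _check_unique_ids(markers: list[Marker]) -> None:
    seen: set[str] = set()
    for mk in markers:
        if mk.id in seen:
            raise PanelFormatError(f"duplicated marker id {mk.id}")
        seen.add(mk.id)


@dataclass
class GenotypePanel:
    """Diploid hard calls for one population over a shared marker map.

    ``calls`` is a samples x markers int8 matrix of counted-allele doses in
    {0, 1, 2} with :data:`MISSING` (-1) for no-calls.
    """

    population: str
    markers: list[Marker]
    samples: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be in {0,1,2} or missing (-1)")
        _check_marker_order(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def subset_markers(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            self.population,
            [self.markers[i] for i in index],
            list(self.samples),
            self.calls[:, index].copy(),
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            self.population,
            list(self.markers),
            [self.samples[i] for i in index],
            self.calls[index, :].copy(),
        )

    def allele_freq(self) -> np.ndarray:
        """Counted-allele frequency per marker over non-missing calls (NaN if none)."""
        obs = self.calls != MISSING
        n = obs.sum(axis=0)
        tot = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, tot / (2.0 * n), np.nan)

    def call_rate(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_markers)
        return (self.calls != MISSING).mean(axis=0)


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotypes serving as an imputation reference (1 = alleleA)."""

    panel_name: str
    markers: list[Marker]
    haplotypes: np.ndarray  # n_haplotypes x n_markers, uint8 in {0,1}

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != len(self.markers):
            raise ValueError("haplotypes must be n_haplotypes x n_markers")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")
        _check_marker_order(self.markers)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def subset_markers(self, index: np.ndarray) -> "HaplotypePanel":
        index = np.asarray(index)
        return HaplotypePanel(
            self.panel_name,
            [self.markers[i] for i in index],
            self.haplotypes[:, index].copy(),
        )

    def allele_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def as_genotypes(self, population: str | None = None) -> GenotypePanel:
        """Pair consecutive haplotypes into diploid individuals."""
        if self.n_haplotypes % 2:
            raise ValueError("odd haplotype count cannot form diploids")
        calls = (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)
        names = [f"{self.panel_name}_ind{i}" for i in range(calls.shape[0])]
        return GenotypePanel(population or self.panel_name, list(self.markers),
                             names, calls)


@dataclass
class PosteriorPanel:
    """Posterior genotype probability triples per sample x marker.

    ``probs[s, k] = (P0, P1, P2)`` is the probability of counted-allele dose
    0, 1, 2 at marker ``k`` for sample ``s``; each triple sums to 1.
    """

    markers: list[Marker]
    samples: list[str]
    probs: np.ndarray  # n_samples x n_markers x 3

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        expect = (len(self.samples), len(self.markers), 3)
        if self.probs.shape != expect:
            raise ValueError(f"probs shape {self.probs.shape} != {expect}")
        if (self.probs < -1e-9).any() or (self.probs > 1 + 1e-9).any():
            raise ValueError("posterior probabilities must lie in [0,1]")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("posterior triples must sum to 1 within 1e-6")

    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]


def dosage_and_bestguess(p: PosteriorPanel) -> tuple[np.ndarray, np.ndarray]:
    """Expected counted-allele dose and best-guess call per genotype.

    dosage = P1 + 2*P2 (in [0, 2]); best-guess = argmax of the triple with
    ties broken toward the smaller dose, so the result is deterministic.
    """
    dosage = p.probs[:, :, 1] + 2.0 * p.probs[:, :, 2]
    best = np.argmax(p.probs, axis=2).astype(np.int8)  # first max wins
    return dosage, best


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_panel(path, format: str, population: str | None = None,
               as_haplotypes: bool = False):
    """Read a genotype or haplotype panel from a text file.

    Parameters
    ----------
    path : str
        Input file. For ``plink_text`` pass the ``.ped`` path; the ``.map``
        file is found by extension substitution.
    format : {"vcf", "plink_text", "oxford_haps"}
    population : label for the resulting panel (default: file stem).
    as_haplotypes : for ``format="vcf"``, require fully phased GTs and
        return a :class:`HaplotypePanel` instead of a genotype panel.
    """
    path = str(path)
    name = population or path.rsplit("/", 1)[-1].split(".")[0]
    if format == "vcf":
        return _read_vcf(path, name, as_haplotypes)
    if format == "plink_text":
        return _read_plink_text(path, name)
    if format == "oxford_haps":
        return _read_oxford_haps(path, name)
    raise ValueError(f"unknown panel format {format!r}")


def _read_vcf(path: str, name: str, as_haplotypes: bool):
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    markers: list[Marker] = []
    rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            raise PanelFormatError(
                f"multi-allelic or non-SNP site {var.ID or var.POS} at "
                f"{var.CHROM}:{var.POS}"
            )
        try:
            markers.append(Marker(var.ID or f"{var.CHROM}:{var.POS}",
                                  str(var.CHROM), int(var.POS),
                                  var.REF, var.ALT[0]))
        except ValueError as exc:
            raise PanelFormatError(str(exc)) from exc
        gts = np.array(var.genotypes, dtype=object)
        a = np.array([g[0] for g in gts])
        b = np.array([g[1] for g in gts])
        if as_haplotypes:
            if not all(len(g) >= 3 and g[2] for g in gts):
                raise PanelFormatError(
                    f"unphased genotype at {var.CHROM}:{var.POS}; phased GTs "
                    "required for a haplotype panel"
                )
            if (a < 0).any() or (b < 0).any():
                raise PanelFormatError(
                    f"missing allele at {var.CHROM}:{var.POS} in phased input")
            # REF (counted) allele coded 1 internally
            hap_rows.append(np.concatenate([(a == 0), (b == 0)]).astype(np.uint8))
        else:
            miss = (a < 0) | (b < 0)
            dose = (a == 0).astype(np.int8) + (b == 0).astype(np.int8)
            dose[miss] = MISSING
            rows.append(dose)
    _check_unique_ids(markers)
    if as_haplotypes:
        haps = (np.array(hap_rows).T if hap_rows
                else np.zeros((2 * len(samples), 0), dtype=np.uint8))
        # interleave so haplotypes 2i, 2i+1 belong to sample i
        order = np.empty(2 * len(samples), dtype=int)
        order[0::2] = np.arange(len(samples))
        order[1::2] = np.arange(len(samples)) + len(samples)
        return HaplotypePanel(name, markers, haps[order])
    calls = (np.array(rows, dtype=np.int8).T if rows
             else np.zeros((len(samples), 0), dtype=np.int8))
    return GenotypePanel(name, markers, samples, calls)


def _read_plink_text(ped_path: str, name: str) -> GenotypePanel:
    map_path = ped_path[:-4] + ".map" if ped_path.endswith(".ped") else ped_path + ".map"
    raw_markers: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise PanelFormatError(f"{map_path}:{lineno}: expected 4 columns")
            raw_markers.append((parts[1], parts[0], int(parts[3])))
    samples: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * len(raw_markers):
                raise PanelFormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * len(raw_markers)} "
                    f"fields, got {len(parts)}"
                )
            samples.append(parts[1])
            allele_rows.append(list(zip(parts[6::2], parts[7::2])))
    markers: list[Marker] = []
    calls = np.full((len(samples), len(raw_markers)), MISSING, dtype=np.int8)
    for k, (mid, chrom, pos) in enumerate(raw_markers):
        seen: list[str] = []
        for pair in (row[k] for row in allele_rows):
            for al in pair:
                if al != "0" and al not in seen:
                    seen.append(al)
        if len(seen) > 2:
            raise PanelFormatError(f"marker {mid}: more than two alleles {seen}")
        while len(seen) < 2:  # monomorphic/empty column: invent the partner
            seen.append(next(b for b in "ACGT" if b not in seen))
        a_allele = seen[0]  # counted allele = first-listed in file order
        try:
            markers.append(Marker(mid, chrom, pos, seen[0], seen[1]))
        except ValueError as exc:
            raise PanelFormatError(f"marker {mid}: {exc}") from exc
        for s, row in enumerate(allele_rows):
            x, y = row[k]
            if x == "0" or y == "0":
                continue
            calls[s, k] = (x == a_allele) + (y == a_allele)
    _check_unique_ids(markers)
    return GenotypePanel(name, markers, samples, calls)


def _read_oxford_haps(path: str, name: str) -> HaplotypePanel:
    """Oxford HAPS-like layout: chrom id pos alleleA alleleB then 0/1 alleles.

    ``0`` codes alleleA in the file; internally 1 = counted allele (alleleA),
    so codes are flipped on read.
    """
    markers: list[Marker] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise PanelFormatError(f"{path}:{lineno}: expected >= 6 columns")
            chrom, mid, pos, a, b = parts[:5]
            try:
                markers.append(Marker(mid, chrom, int(pos), a, b))
            except ValueError as exc:
                raise PanelFormatError(f"{path}:{lineno}: {exc}") from exc
            try:
                codes = np.array(parts[5:], dtype=np.uint8)
            except ValueError as exc:
                raise PanelFormatError(f"{path}:{lineno}: non-numeric allele") from exc
            if not np.isin(codes, (0, 1)).all():
                raise PanelFormatError(f"{path}:{lineno}: alleles must be 0/1")
            rows.append(1 - codes)
    _check_unique_ids(markers)
    if rows and len({len(r) for r in rows}) > 1:
        raise PanelFormatError(f"{path}: ragged haplotype rows")
    haps = np.array(rows, dtype=np.uint8).T if rows else np.zeros((0, 0), np.uint8)
    return HaplotypePanel(name, markers, haps)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_vcf(panel, path) -> None:
    """Write a GenotypePanel (GT 0/0-style) or HaplotypePanel (phased) as VCF 4.2."""
    is_hap = isinstance(panel, HaplotypePanel)
    if is_hap:
        if panel.n_haplotypes % 2:
            raise ValueError("odd haplotype count cannot be written as diploid VCF")
        samples = [f"{panel.panel_name}_ind{i}" for i in range(panel.n_haplotypes // 2)]
    else:
        samples = panel.samples
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for k, mk in enumerate(panel.markers):
            if is_hap:
                # internal 1 = counted = REF -> VCF allele index 0
                codes = 1 - panel.haplotypes[:, k]
                gts = [f"{codes[2 * i]}|{codes[2 * i + 1]}"
                       for i in range(len(samples))]
            else:
                lut = {2: "0/0", 1: "0/1", 0: "1/1", MISSING: "./."}
                gts = [lut[int(c)] for c in panel.calls[:, k]]
            fh.write(f"{mk.chrom}\t{mk.pos}\t{mk.id}\t{mk.alleleA}\t{mk.alleleB}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


def write_posteriors(p: PosteriorPanel, path, dialect: str) -> None:
    """Serialize a PosteriorPanel.

    ``oxford_gen``: one line per marker -- five leading columns
    (snp id, rs id, position, alleleA, alleleB) then ``P0 P1 P2`` per sample
    in counted-allele dose order.
    ``mach_mlprob``: one row per sample -- id, the literal tag ``ML_PROB``,
    then ``P0 P1`` per marker; ``P2`` is implied as ``1 - P0 - P1``.
    """
    if dialect == "oxford_gen":
        with open(path, "w", newline="\n") as fh:
            for k, mk in enumerate(p.markers):
                lead = f"{mk.id} {mk.id} {mk.pos} {mk.alleleA} {mk.alleleB}"
                probs = " ".join(
                    f"{_fmt(p.probs[s, k, 0])} {_fmt(p.probs[s, k, 1])} "
                    f"{_fmt(p.probs[s, k, 2])}"
                    for s in range(len(p.samples))
                )
                fh.write(f"{lead} {probs}\n")
    elif dialect == "mach_mlprob":
        with open(path, "w", newline="\n") as fh:
            for s, sample in enumerate(p.samples):
                pairs = " ".join(
                    f"{_fmt(p.probs[s, k, 0])} {_fmt(p.probs[s, k, 1])}"
                    for k in range(len(p.markers))
                )
                fh.write(f"{sample} ML_PROB {pairs}\n")
    else:
        raise ValueError(f"unknown posterior dialect {dialect!r}")


def _normalize_triples(probs: np.ndarray, where: str) -> np.ndarray:
    if (probs < -1e-12).any():
        raise PanelFormatError(f"{where}: negative probability")
    sums = probs.sum(axis=-1)
    if ((sums < 0.99) | (sums > 1.01)).any():
        bad = float(sums[(sums < 0.99) | (sums > 1.01)].flat[0])
        raise PanelFormatError(
            f"{where}: probability triple sums to {bad:.4g}, outside [0.99, 1.01]")
    return np.clip(probs, 0.0, None) / sums[..., None]


def read_posteriors(path, dialect: str,
                    markers: list[Marker] | None = None,
                    samples: list[str] | None = None) -> PosteriorPanel:
    """Read posterior triples; triples are renormalized if their sum lies in
    [0.99, 1.01] and rejected otherwise.

    ``mach_mlprob`` carries no marker map of its own, so ``markers`` must be
    supplied for that dialect.
    """
    path = str(path)
    if dialect == "oxford_gen":
        mks: list[Marker] = []
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                parts = line.split()
                if not parts:
                    continue
                if (len(parts) - 5) % 3:
                    raise PanelFormatError(
                        f"{path}:{lineno}: probability fields not a multiple of 3")
                mid, _, pos, a, b = parts[:5]
                chrom = markers[len(mks)].chrom if markers else "0"
                mks.append(Marker(mid, chrom, int(pos), a, b))
                vals = np.array(parts[5:], dtype=float).reshape(-1, 3)
                rows.append(_normalize_triples(vals, f"{path}:{lineno}"))
        n_samples = rows[0].shape[0] if rows else 0
        names = samples or [f"sample{i}" for i in range(n_samples)]
        probs = (np.stack(rows, axis=1) if rows
                 else np.zeros((len(names), 0, 3)))
        return PosteriorPanel(mks, names, probs)
    if dialect == "mach_mlprob":
        if markers is None:
            raise ValueError("mach_mlprob carries no marker map; pass markers=")
        names: list[str] = []
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                parts = line.split()
                if not parts:
                    continue
                names.append(parts[0])
                vals = np.array(parts[2:], dtype=float).reshape(-1, 2)
                if vals.shape[0] != len(markers):
                    raise PanelFormatError(
                        f"{path}:{lineno}: {vals.shape[0]} genotypes for "
                        f"{len(markers)} markers")
                # text rounding can push P0+P1 a hair over 1
                p2 = np.clip(1.0 - vals.sum(axis=1), 0.0, None)
                triples = np.column_stack([vals, p2])
                rows.append(_normalize_triples(triples, f"{path}:{lineno}"))
        probs = np.array(rows) if rows else np.zeros((0, len(markers), 3))
        return PosteriorPanel(list(markers), names, probs)
    raise ValueError(f"unknown posterior dialect {dialect!r}")
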