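"""Data model and readers/writers for diploid microsatellite datasets.

The central container is :class:`GenotypeDataset`: individuals x loci diploid
allele-size calls (base pairs) plus population and maternal-family metadata.
GENEPOP text files (2- or 3-digit allele coding) and a small CSV dialect for
population metadata (coordinates, grove area, grouping) are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for a missing allele call in integer arrays


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass(frozen=True)
class LocusDef:
    """A microsatellite locus: name, repeat-motif length (bp) and valid size range.

    ``offset`` is the non-repeat flanking length in bp; repeat counts are
    ``(size - offset) / motif_length``.  It defaults to 0, in which case allele
    sizes are interpreted as already being proportional to repeat number.
    """

    name: str
    motif_length: int = 2
    valid_size_range: tuple[int, int] = (0, 10_000)
    offset: int = 0

    def __post_init__(self) -> None:
        if self.motif_length not in (2, 3):
            raise ValueError(f"motif_length must be 2 or 3, got {self.motif_length}")
        lo, hi = self.valid_size_range
        if not lo < hi:
            raise ValueError(f"invalid size range {self.valid_size_range}")

    def repeat_units(self, size_bp: np.ndarray | int) -> np.ndarray | float:
        """Convert allele size(s) in bp to repeat units (missing passes through)."""
        size_bp = np.asarray(size_bp)
        out = (size_bp - self.offset) / self.motif_length
        return np.where(size_bp == MISSING, MISSING, out)


@dataclass(frozen=True)
class GenotypeRecord:
    """One diploid individual: ordered per-locus pairs of allele sizes (bp)."""

    individual_id: str
    population_id: str
    calls: tuple[tuple[int, int], ...]
    family_id: str | None = None

    def __post_init__(self) -> None:
        for a, b in self.calls:
            if (a == MISSING) != (b == MISSING):
                raise ValueError(
                    f"{self.individual_id}: half-missing genotype ({a},{b})"
                )


@dataclass(frozen=True)
class PopulationMeta:
    population_id: str
    latitude: float
    longitude: float
    grove_area: float  # hectares
    group_label: str = ""

    def __post_init__(self) -> None:
        if abs(self.latitude) > 90:
            raise ValueError(f"latitude {self.latitude} out of range")
        if abs(self.longitude) > 180:
            raise ValueError(f"longitude {self.longitude} out of range")
        if self.grove_area <= 0:
            raise ValueError(f"grove_area must be positive, got {self.grove_area}")


@dataclass
class GenotypeDataset:
    """Diploid codominant genotypes for a set of populations.

    Invariants: every record has one call pair per locus; every record's
    population appears in ``meta`` when metadata are attached.
    """

    loci: list[LocusDef]
    records: list[GenotypeRecord]
    meta: list[PopulationMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        nl = len(self.loci)
        for r in self.records:
            if len(r.calls) != nl:
                raise ValueError(
                    f"{r.individual_id}: {len(r.calls)} call pairs for {nl} loci"
                )
        if self.meta:
            known = {m.population_id for m in self.meta}
            missing = {r.population_id for r in self.records} - known
            if missing:
                raise ValueError(f"populations without metadata: {sorted(missing)}")

    # -- array views -------------------------------------------------------

    @property
    def population_ids(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.population_id, None)
        return list(seen)

    def allele_array(self) -> np.ndarray:
        """(n_individuals, n_loci, 2) int array of allele sizes; MISSING = -1."""
        return np.array([r.calls for r in self.records], dtype=np.int64)

    def population_codes(self) -> np.ndarray:
        """Integer population code per individual, in ``population_ids`` order."""
        idx = {p: i for i, p in enumerate(self.population_ids)}
        return np.array([idx[r.population_id] for r in self.records], dtype=np.int64)

    def repeat_array(self) -> np.ndarray:
        """(n, L, 2) float array of repeat units; MISSING preserved as -1."""
        bp = self.allele_array().astype(float)
        out = np.empty_like(bp)
        for j, loc in enumerate(self.loci):
            out[:, j] = loc.repeat_units(bp[:, j])
        return out

    def subset_populations(self, keep: list[str]) -> "GenotypeDataset":
        keep_set = set(keep)
        recs = [r for r in self.records if r.population_id in keep_set]
        meta = [m for m in self.meta if m.population_id in keep_set]
        return GenotypeDataset(self.loci, recs, meta)

    def subset_individuals(self, keep_ids: list[str]) -> "GenotypeDataset":
        keep_set = set(keep_ids)
        recs = [r for r in self.records if r.individual_id in keep_set]
        pops = {r.population_id for r in recs}
        meta = [m for m in self.meta if m.population_id in pops]
        return GenotypeDataset(self.loci, recs, meta)

    def sample_sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.population_id] = out.get(r.population_id, 0) + 1
        return out


# -- GENEPOP ---------------------------------------------------------------


def _parse_genepop_genotype(tok: str, digits: int, missing_code: str) -> tuple[int, int]:
    if len(tok) != 2 * digits:
        raise FormatError(f"genotype token {tok!r} is not {2 * digits} digits")
    a, b = tok[:digits], tok[digits:]
    miss = missing_code.zfill(digits)
    a_v = MISSING if a == miss else int(a)
    b_v = MISSING if b == miss else int(b)
    if (a_v == MISSING) != (b_v == MISSING):
        # GENEPOP treats a genotype with one null side as missing
        a_v = b_v = MISSING
    return a_v, b_v


def read_genepop(path, missing_code: str = "000", offset: int = 0,
                 motif_lengths: list[int] | None = None) -> GenotypeDataset:
    """Read a GENEPOP file (2- or 3-digit coding, comma or whitespace genotypes).

    Populations are named from the label of the first individual in each POP
    block, following GENEPOP convention.  ``offset`` is stored on every locus
    for bp -> repeat-unit conversion.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise FormatError("empty GENEPOP file")
    body = lines[1:]  # first line is a title/comment

    locus_names: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        chunk = body[i].strip()
        if chunk:
            locus_names.extend(n.strip() for n in chunk.split(",") if n.strip())
        i += 1
    if not locus_names:
        raise FormatError("no locus names before first POP")

    records: list[GenotypeRecord] = []
    pop_counter = 0
    pop_name: str | None = None
    digits: int | None = None
    for ln in body[i:]:
        s = ln.strip()
        if not s:
            continue
        if s.upper() == "POP":
            pop_counter += 1
            pop_name = None
            continue
        if "," not in s:
            raise FormatError(f"individual line without comma: {s!r}")
        label, geno = s.split(",", 1)
        label = label.strip()
        toks = geno.split()
        if len(toks) != len(locus_names):
            raise FormatError(
                f"{label}: {len(toks)} genotypes for {len(locus_names)} loci"
            )
        if digits is None:
            w = len(toks[0])
            if w not in (4, 6):
                raise FormatError(f"genotype token {toks[0]!r} has odd width {w}")
            digits = w // 2
        if pop_name is None:
            pop_name = label
        calls = tuple(
            _parse_genepop_genotype(t, digits, missing_code) for t in toks
        )
        records.append(GenotypeRecord(label, pop_name, calls))
    motifs = motif_lengths or [2] * len(locus_names)
    loci = [
        LocusDef(nm, motif_length=m, offset=offset)
        for nm, m in zip(locus_names, motifs)
    ]
    return GenotypeDataset(loci, records)


def write_genepop(dataset: GenotypeDataset, path, title: str = "msatabc export",
                  digits: int = 3, missing_code: str = "000") -> None:
    """Write a GENEPOP file with 3-digit coding (populations in meta order)."""
    arr = dataset.allele_array()
    if arr.size and arr.max() >= 10 ** digits:
        raise ValueError(f"allele size {arr.max()} not encodable in {digits} digits")
    miss = missing_code.zfill(digits)

    def enc(v: int) -> str:
        return miss if v == MISSING else str(v).zfill(digits)

    with open(path, "w") as fh:
        fh.write(title + "\n")
        for loc in dataset.loci:
            fh.write(loc.name + "\n")
        for pop in dataset.population_ids:
            fh.write("POP\n")
            for r in dataset.records:
                if r.population_id != pop:
                    continue
                geno = " ".join(enc(a) + enc(b) for a, b in r.calls)
                fh.write(f"{r.individual_id}, {geno}\n")


# -- population metadata ---------------------------------------------------


def read_population_meta(csv_path) -> list[PopulationMeta]:
    """Read population metadata CSV (population_id, lat, long, area, group)."""
    try:
        df = pd.read_csv(csv_path)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    required = {"population_id", "lat", "long", "area"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata CSV missing columns: {sorted(missing)}")
    if df["population_id"].duplicated().any():
        dups = df.loc[df["population_id"].duplicated(), "population_id"].tolist()
        raise FormatError(f"duplicate population_id: {dups}")
    for col in ("lat", "long", "area"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"non-numeric values in column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PopulationMeta(
                population_id=str(row.population_id),
                latitude=float(row.lat),
                longitude=float(getattr(row, "long")),
                grove_area=float(row.area),
                group_label=str(getattr(row, "group", "")) if "group" in df.columns else "",
            )
        )
    return out


# -- validation ------------------------------------------------------------


@dataclass
class ValidationReport:
    congruence_warnings: list[str]
    missing_fraction: float
    sample_sizes: dict[str, int]

    @property
    def ok(self) -> bool:
        return not self.congruence_warnings


def validate_dataset(dataset: GenotypeDataset) -> ValidationReport:
    """Report allele sizes incongruent with the repeat motif, missingness and n.

    Report-only: the dataset is never mutated.  An allele is flagged when its
    size minus the locus offset is not a multiple of the motif length (an
    off-ladder call, or a wrong offset).
    """
    arr = dataset.allele_array()
    warnings: list[str] = []
    for j, loc in enumerate(dataset.loci):
        sizes = arr[:, j].ravel()
        sizes = sizes[sizes != MISSING]
        bad = np.unique(sizes[(sizes - loc.offset) % loc.motif_length != 0])
        for b in bad:
            warnings.append(
                f"locus {loc.name}: allele {b} bp incongruent with "
                f"motif {loc.motif_length} (offset {loc.offset})"
            )
    n_calls = arr.shape[0] * arr.shape[1] if arr.size else 0
    n_missing = int((arr[:, :, 0] == MISSING).sum()) if arr.size else 0
    frac = n_missing / n_calls if n_calls else 0.0
    return ValidationReport(warnings, frac, dataset.sample_sizes())
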