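"""PLINK genotype I/O, panel merging and missingness quality control.

Genotypes are stored as allele-B dosage (0, 1, 2 copies of ``allele_b``)
in an ``int8`` matrix with :data:`MISSING` (= -1) marking no-calls.  Both
the text dialect (.ped/.map) and the SNP-major binary dialect
(.bed/.bim/.fam, magic bytes ``0x6c 0x1b 0x01``) are supported and
round-trip exactly, including missing-call placement.

The breed label of each animal is carried in the PLINK family-ID column,
the only label-bearing slot the format offers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING: int = -1
"""Sentinel for a missing genotype call."""

AUTOSOMES = frozenset(range(1, 19))
"""Pig autosomes in scope (SSC1-SSC18)."""

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "0": "0"}
_VALID_ALLELES = frozenset("ACGT0")


class PlinkFormatError(ValueError):
    """Raised when PLINK files are malformed or mutually inconsistent."""


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNP: identifier, map position and the two alleles.

    ``allele_a``/``allele_b`` correspond to PLINK A1/A2; dosages count
    copies of ``allele_b``.
    """

    snp_id: str
    chromosome: int
    position_bp: int
    allele_a: str = "A"
    allele_b: str = "B"

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValueError("snp_id must be non-empty")
        if self.position_bp < 0:
            raise ValueError(f"negative position for {self.snp_id}")

    @property
    def is_strand_ambiguous(self) -> bool:
        """True for A/T and C/G SNPs, which cannot be strand-resolved."""
        return {self.allele_a, self.allele_b} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class Sample:
    sample_id: str
    breed: str


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-count matrix with sample and SNP metadata.

    ``calls[i, j]`` is the number of copies of ``snps[j].allele_b`` carried
    by ``samples[i]``, or :data:`MISSING`.
    """

    samples: list[Sample]
    snps: list[SnpRecord]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid genotype codes at {np.argwhere(bad)[:5]}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id")
        sids = [s.snp_id for s in self.snps]
        if len(set(sids)) != len(sids):
            raise ValueError("duplicate snp_id")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def m(self) -> int:
        return len(self.snps)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def breeds(self) -> np.ndarray:
        return np.array([s.breed for s in self.samples], dtype=object)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def subset(self, rows=None, cols=None) -> "GenotypeMatrix":
        rows = np.arange(self.n) if rows is None else np.asarray(rows)
        cols = np.arange(self.m) if cols is None else np.asarray(cols)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in rows],
            snps=[self.snps[j] for j in cols],
            calls=self.calls[np.ix_(rows, cols)],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.snps == other.snps
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class QcReport:
    """Record of the missingness filter: who was removed and why."""

    samples_removed: list[tuple[str, float]] = field(default_factory=list)
    snps_removed: list[tuple[str, float]] = field(default_factory=list)
    max_sample_missing: float = 0.10
    max_snp_missing: float = 0.05
    n_before: int = 0
    n_after: int = 0
    m_before: int = 0
    m_after: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"entity": "sample", "id": sid, "missing_fraction": f, "action": "removed"}
            for sid, f in self.samples_removed
        ] + [
            {"entity": "snp", "id": sid, "missing_fraction": f, "action": "removed"}
            for sid, f in self.snps_removed
        ]
        return pd.DataFrame(rows, columns=["entity", "id", "missing_fraction", "action"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class MergeReport:
    n_common: int = 0
    n_dropped_non_autosomal: int = 0
    n_dropped_ambiguous: int = 0
    n_dropped_irreconcilable: int = 0
    dropped_snp_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# reading


def read_plink(path_prefix, dialect: str = "auto") -> GenotypeMatrix:
    """Read a PLINK fileset ``<prefix>.ped/.map`` or ``<prefix>.bed/.bim/.fam``.

    Parameters
    ----------
    path_prefix : str or Path
        Path without extension.
    dialect : {"auto", "text", "binary"}
        ``auto`` picks binary if a .bed file exists, else text.
    """
    prefix = Path(path_prefix)
    if dialect == "auto":
        dialect = "binary" if prefix.with_suffix(".bed").exists() else "text"
    if dialect == "text":
        return _read_ped_map(prefix)
    if dialect == "binary":
        return _read_bed(prefix)
    raise ValueError(f"unknown dialect {dialect!r}")


def _parse_chromosome(token: str, path) -> int:
    try:
        return int(token)
    except ValueError:
        raise PlinkFormatError(f"{path}: non-numeric chromosome {token!r}") from None


def _read_map(path: Path) -> list[SnpRecord]:
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise PlinkFormatError(f"{path}:{ln}: expected >=4 columns")
            records.append(
                SnpRecord(
                    snp_id=parts[1],
                    chromosome=_parse_chromosome(parts[0], path),
                    position_bp=int(parts[3]),
                )
            )
    return records


def _read_ped_map(prefix: Path) -> GenotypeMatrix:
    map_path, ped_path = prefix.with_suffix(".map"), prefix.with_suffix(".ped")
    snps = _read_map(map_path)
    m = len(snps)
    samples: list[Sample] = []
    allele_pairs: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise PlinkFormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            samples.append(Sample(sample_id=parts[1], breed=parts[0]))
            pairs = list(zip(parts[6::2], parts[7::2]))
            for a1, a2 in pairs:
                if a1 not in _VALID_ALLELES or a2 not in _VALID_ALLELES:
                    raise PlinkFormatError(
                        f"{ped_path}:{ln}: unknown allele characters {a1!r}/{a2!r}"
                    )
            allele_pairs.append(pairs)

    # infer per-SNP alleles: allele_b is the lexically later observed allele
    # unless the .map dialect carried none (text PLINK stores alleles only in
    # the .ped body).
    calls = np.full((len(samples), m), MISSING, dtype=np.int8)
    resolved: list[SnpRecord] = []
    for j, snp in enumerate(snps):
        observed = sorted(
            {a for pairs in allele_pairs for a in pairs[j] if a != "0"}
        )
        if len(observed) > 2:
            raise PlinkFormatError(f"SNP {snp.snp_id}: >2 alleles {observed}")
        if len(observed) == 0:
            a, b = "0", "0"
        elif len(observed) == 1:
            a, b = observed[0], "0"
        else:
            a, b = observed
        resolved.append(
            SnpRecord(snp.snp_id, snp.chromosome, snp.position_bp, a, b)
        )
        for i, pairs in enumerate(allele_pairs):
            a1, a2 = pairs[j]
            if a1 == "0" or a2 == "0":
                continue  # partial calls treated as missing
            calls[i, j] = (a1 == b) + (a2 == b)
    return GenotypeMatrix(samples=samples, snps=resolved, calls=calls)


def _read_fam(path: Path) -> list[Sample]:
    samples = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise PlinkFormatError(f"{path}:{ln}: expected >=2 columns")
            samples.append(Sample(sample_id=parts[1], breed=parts[0]))
    return samples


def _read_bim(path: Path) -> list[SnpRecord]:
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise PlinkFormatError(f"{path}:{ln}: expected 6 columns")
            a1, a2 = parts[4], parts[5]
            if a1 not in _VALID_ALLELES or a2 not in _VALID_ALLELES:
                raise PlinkFormatError(f"{path}:{ln}: unknown alleles {a1!r}/{a2!r}")
            records.append(
                SnpRecord(
                    snp_id=parts[1],
                    chromosome=_parse_chromosome(parts[0], path),
                    position_bp=int(parts[3]),
                    allele_a=a1,
                    allele_b=a2,
                )
            )
    return records


# .bed two-bit codes (SNP-major): 00 hom A1, 01 missing, 10 het, 11 hom A2.
_BED_MAGIC = b"\x6c\x1b\x01"
_CODE_TO_CALL = np.array([0, MISSING, 1, 2], dtype=np.int8)
_CALL_TO_CODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


def _read_bed(prefix: Path) -> GenotypeMatrix:
    samples = _read_fam(prefix.with_suffix(".fam"))
    snps = _read_bim(prefix.with_suffix(".bim"))
    n, m = len(samples), len(snps)
    data = prefix.with_suffix(".bed").read_bytes()
    if data[:3] != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes {data[:3]!r}")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(data, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise PlinkFormatError(
            f"{prefix}.bed: size {body.size} != {bytes_per_snp} bytes x {m} SNPs"
        )
    body = body.reshape(m, bytes_per_snp)
    # unpack two-bit codes, little-endian within each byte
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    calls = _CODE_TO_CALL[codes].T.copy()
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


# ---------------------------------------------------------------------------
# writing


def write_plink(g: GenotypeMatrix, path_prefix, dialect: str = "binary") -> None:
    """Write ``g`` as a PLINK fileset; re-reading yields an equal matrix."""
    if g.n == 0 or g.m == 0:
        raise ValueError("refusing to write an empty GenotypeMatrix")
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "text":
        _write_ped_map(g, prefix)
    elif dialect == "binary":
        _write_bed(g, prefix)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_ped_map(g: GenotypeMatrix, prefix: Path) -> None:
    with open(prefix.with_suffix(".map"), "w") as fh:
        for s in g.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position_bp}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, smp in enumerate(g.samples):
            fields = [smp.breed, smp.sample_id, "0", "0", "0", "-9"]
            for j, snp in enumerate(g.snps):
                c = g.calls[i, j]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [snp.allele_a, snp.allele_a]
                elif c == 1:
                    fields += [snp.allele_a, snp.allele_b]
                else:
                    fields += [snp.allele_b, snp.allele_b]
            fh.write(" ".join(fields) + "\n")


def _write_bed(g: GenotypeMatrix, prefix: Path) -> None:
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for smp in g.samples:
            fh.write(f"{smp.breed} {smp.sample_id} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for s in g.snps:
            fh.write(
                f"{s.chromosome}\t{s.snp_id}\t0\t{s.position_bp}\t"
                f"{s.allele_a}\t{s.allele_b}\n"
            )
    n, m = g.n, g.m
    bytes_per_snp = (n + 3) // 4
    code_lut = np.zeros(4, dtype=np.uint8)
    for call, code in _CALL_TO_CODE.items():
        code_lut[call % 4] = code  # MISSING=-1 maps to index 3
    codes = code_lut[g.calls.T % 4].astype(np.uint8)  # m x n
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    shifts = np.arange(4, dtype=np.uint8) * 2
    packed = (
        (padded.reshape(m, bytes_per_snp, 4) << shifts[None, None, :])
        .sum(axis=2)
        .astype(np.uint8)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# merging and QC


def _harmonize(snp_a: SnpRecord, snp_b: SnpRecord) -> str | None:
    """How to recode panel-b calls onto panel-a's allele frame.

    Returns "keep", "swap" (calls -> 2-g) or None (irreconcilable / ambiguous).
    """
    a1, a2 = snp_a.allele_a, snp_a.allele_b
    b1, b2 = snp_b.allele_a, snp_b.allele_b
    if (a1, a2) == (b1, b2):
        return "keep"
    if snp_a.is_strand_ambiguous or snp_b.is_strand_ambiguous:
        # labels disagree and strand cannot disambiguate
        return None
    if (a1, a2) == (b2, b1):
        return "swap"
    c1, c2 = _COMPLEMENT.get(b1), _COMPLEMENT.get(b2)
    if (a1, a2) == (c1, c2):
        return "keep"
    if (a1, a2) == (c2, c1):
        return "swap"
    return None


def merge_panels(
    a: GenotypeMatrix, b: GenotypeMatrix, return_report: bool = False
):
    """Merge two panels on their common autosomal SNPs, harmonizing alleles.

    SNP metadata (position, allele frame) is taken from panel ``a``; panel-b
    calls are recoded ``2 - g`` where its allele labels are swapped relative
    to ``a`` (directly or on the opposite strand).  Strand-ambiguous SNPs
    (A/T, C/G) with discordant labels, and SNPs with irreconcilable alleles,
    are dropped with a warning.
    """
    report = MergeReport()
    idx_b = {s.snp_id: j for j, s in enumerate(b.snps)}
    keep_a, keep_b, actions = [], [], []
    for j, snp in enumerate(a.snps):
        if snp.snp_id not in idx_b:
            continue
        if snp.chromosome not in AUTOSOMES or b.snps[idx_b[snp.snp_id]].chromosome not in AUTOSOMES:
            report.n_dropped_non_autosomal += 1
            continue
        report.n_common += 1
        action = _harmonize(snp, b.snps[idx_b[snp.snp_id]])
        if action is None:
            if snp.is_strand_ambiguous:
                report.n_dropped_ambiguous += 1
            else:
                report.n_dropped_irreconcilable += 1
            report.dropped_snp_ids.append(snp.snp_id)
            continue
        keep_a.append(j)
        keep_b.append(idx_b[snp.snp_id])
        actions.append(action)
    if report.dropped_snp_ids:
        warnings.warn(
            f"merge_panels dropped {len(report.dropped_snp_ids)} SNPs "
            f"({report.n_dropped_ambiguous} strand-ambiguous, "
            f"{report.n_dropped_irreconcilable} irreconcilable)"
        )
    calls_a = a.calls[:, keep_a]
    calls_b = b.calls[:, keep_b].copy()
    swap = np.array([act == "swap" for act in actions], dtype=bool)
    if swap.any():
        col = calls_b[:, swap]
        recoded = (2 - col).astype(np.int8)
        recoded[col == MISSING] = MISSING
        calls_b[:, swap] = recoded
    ids_a = {s.sample_id for s in a.samples}
    b_samples = []
    for s in b.samples:
        if s.sample_id in ids_a:
            b_samples.append(Sample(f"{s.sample_id}:2", s.breed))
        else:
            b_samples.append(s)
    if any(s1.sample_id != s2.sample_id for s1, s2 in zip(b_samples, b.samples)):
        warnings.warn("duplicate sample_ids across panels; suffixed ':2'")
    merged = GenotypeMatrix(
        samples=a.samples + b_samples,
        snps=[a.snps[j] for j in keep_a],
        calls=np.vstack([calls_a, calls_b]),
    )
    return (merged, report) if return_report else merged


class EmptyAfterQcError(ValueError):
    """All samples (or SNPs) were removed by the missingness filter."""


def qc_filter(
    g: GenotypeMatrix,
    max_sample_missing: float = 0.10,
    max_snp_missing: float = 0.05,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop samples then SNPs exceeding the missingness thresholds.

    Samples with a missing fraction *strictly greater than*
    ``max_sample_missing`` are removed first; SNP missingness is then
    recomputed on the surviving samples and SNPs strictly above
    ``max_snp_missing`` removed.  Boundary values are retained.
    """
    if not (0 <= max_sample_missing <= 1 and 0 <= max_snp_missing <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    report = QcReport(
        max_sample_missing=max_sample_missing,
        max_snp_missing=max_snp_missing,
        n_before=g.n,
        m_before=g.m,
    )
    miss = g.missing_mask()
    sample_frac = miss.mean(axis=1)
    keep_rows = sample_frac <= max_sample_missing
    report.samples_removed = [
        (g.samples[i].sample_id, float(sample_frac[i]))
        for i in np.flatnonzero(~keep_rows)
    ]
    if not keep_rows.any():
        raise EmptyAfterQcError("no samples left after the sample-missingness filter")
    snp_frac = miss[keep_rows].mean(axis=0)
    keep_cols = snp_frac <= max_snp_missing
    report.snps_removed = [
        (g.snps[j].snp_id, float(snp_frac[j])) for j in np.flatnonzero(~keep_cols)
    ]
    if not keep_cols.any():
        raise EmptyAfterQcError("no SNPs left after the SNP-missingness filter")
    out = g.subset(np.flatnonzero(keep_rows), np.flatnonzero(keep_cols))
    report.n_after, report.m_after = out.n, out.m
    return out, report


def mean_impute(g: GenotypeMatrix) -> np.ndarray:
    """Replace missing calls by the per-SNP mean of observed calls.

    Returns a float matrix; observed cells are unchanged.  A SNP with no
    observed call at all is an error (it should have been removed by QC).
    """
    x = g.calls.astype(np.float64)
    miss = g.missing_mask()
    n_obs = (~miss).sum(axis=0)
    if (n_obs == 0).any():
        bad = [g.snps[j].snp_id for j in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"SNPs with zero observed calls: {bad[:5]}")
    x[miss] = np.nan
    col_means = np.nanmean(x, axis=0)
    rows, cols = np.nonzero(miss)
    x[rows, cols] = col_means[cols]
    return x
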