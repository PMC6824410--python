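"""PLINK-layout genotype I/O, quality control, and breed allele frequencies.

SNP-array genotypes are held as a samples x SNPs dosage matrix (count of the
reference allele, 0/1/2, NaN for missing) together with a physical map and
per-sample breed labels.  Both the PED/MAP text layout and the binary
BED/BIM/FAM triple (v1.00 magic bytes, SNP-major) are supported.

Coordinates are 1-based; all intervals in this package are closed
[start_bp, end_bp].  Dosage polarity is reproducible from the files alone:
the reference allele is taken from a 6-column map (or .bim) when present,
otherwise it is the first allele encountered in PED file order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SnpMap",
    "GenotypeDataset",
    "QCReport",
    "AlleleFrequencyPanel",
    "read_plink",
    "write_plink",
    "qc_filter",
    "breed_allele_frequencies",
]

#: autosome labels for Ovis aries
SHEEP_AUTOSOMES = frozenset(range(1, 27))

MISSING = np.nan


class PlinkParseError(ValueError):
    """Malformed PED/MAP/BED content; message names the offending line."""


class EmptyAfterQCError(ValueError):
    """Every sample or every SNP was removed by quality control."""


@dataclass(frozen=True)
class SnpMap:
    """Physical map: SNP identifiers with chromosome and 1-based bp position."""

    snp_id: np.ndarray        # str array, shape (L,)
    chromosome: np.ndarray    # int array, shape (L,)
    position_bp: np.ndarray   # int array, shape (L,)

    def __post_init__(self):
        sid = np.asarray(self.snp_id, dtype=object)
        chrom = np.asarray(self.chromosome, dtype=np.int64)
        pos = np.asarray(self.position_bp, dtype=np.int64)
        if not (len(sid) == len(chrom) == len(pos)):
            raise ValueError("snp_id, chromosome, position_bp must have equal length")
        object.__setattr__(self, "snp_id", sid)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position_bp", pos)
        for c in np.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    def subset(self, mask_or_index) -> "SnpMap":
        return SnpMap(self.snp_id[mask_or_index],
                      self.chromosome[mask_or_index],
                      self.position_bp[mask_or_index])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"snp_id": self.snp_id,
                             "chromosome": self.chromosome,
                             "position_bp": self.position_bp})


@dataclass
class GenotypeDataset:
    """Diploid biallelic genotypes for a labelled cohort.

    ``dosages[i, j]`` counts copies of SNP ``j``'s reference allele carried by
    sample ``i`` (0, 1, 2) with NaN marking a missing call.  ``alleles`` maps
    each SNP to its (reference, alternate) character codes, defaulting to
    ('A', 'B') for simulated data.
    """

    sample_id: np.ndarray     # str, shape (n,)
    breed: np.ndarray         # str, shape (n,)
    snp_map: SnpMap
    dosages: np.ndarray       # float, shape (n, L); values in {0,1,2,NaN}
    alleles: np.ndarray | None = None   # object array shape (L, 2)

    def __post_init__(self):
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        self.breed = np.asarray(self.breed, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, L = self.dosages.shape
        if n != len(self.sample_id) or n != len(self.breed):
            raise ValueError("dosage rows do not match sample count")
        if L != self.snp_map.n_snps:
            raise ValueError("dosage columns do not match SNP count")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")
        if self.alleles is None:
            al = np.empty((L, 2), dtype=object)
            al[:, 0], al[:, 1] = "A", "B"
            self.alleles = al
        else:
            self.alleles = np.asarray(self.alleles, dtype=object).reshape(L, 2)

    @property
    def n_samples(self) -> int:
        return len(self.sample_id)

    @property
    def n_snps(self) -> int:
        return self.snp_map.n_snps

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.dosages).sum())

    def breeds(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.breed:
            seen.setdefault(b, None)
        return list(seen)

    def subset(self, sample_mask=None, snp_mask=None) -> "GenotypeDataset":
        smask = slice(None) if sample_mask is None else sample_mask
        lmask = slice(None) if snp_mask is None else snp_mask
        return GenotypeDataset(
            self.sample_id[smask], self.breed[smask],
            self.snp_map.subset(lmask) if snp_mask is not None else self.snp_map,
            self.dosages[smask][:, lmask],
            self.alleles[lmask] if snp_mask is not None else self.alleles,
        )

    def samples_of(self, breed: str) -> np.ndarray:
        mask = self.breed == breed
        if not mask.any():
            raise KeyError(f"unknown breed label: {breed!r}")
        return mask


@dataclass
class QCReport:
    """Itemised record of what quality control removed, and why.

    Each removed sample/SNP carries exactly one primary reason: the first
    failed filter in the fixed order mind -> geno -> maf -> autosome.
    """

    mind: float
    geno: float
    maf: float
    autosomes_only: bool
    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    removed_snps: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("sample", i, r) for i, r in self.removed_samples]
        rows += [("snp", i, r) for i, r in self.removed_snps]
        return pd.DataFrame(rows, columns=["kind", "id", "reason"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class AlleleFrequencyPanel:
    """Per-SNP reference-allele frequencies of the two ancestral proxies.

    ``freq_a`` is the Merino-side proxy (ancestry A), ``freq_b`` the
    non-Merino proxy (ancestry B).
    """

    snp_map: SnpMap
    freq_a: np.ndarray
    freq_b: np.ndarray

    def __post_init__(self):
        self.freq_a = np.asarray(self.freq_a, dtype=float)
        self.freq_b = np.asarray(self.freq_b, dtype=float)
        L = self.snp_map.n_snps
        if self.freq_a.shape != (L,) or self.freq_b.shape != (L,):
            raise ValueError("panel frequencies must align with the SNP map")
        for f in (self.freq_a, self.freq_b):
            fin = f[np.isfinite(f)]
            if fin.size and (fin.min() < 0 or fin.max() > 1):
                raise ValueError("allele frequencies must lie in [0, 1]")

    def swapped(self) -> "AlleleFrequencyPanel":
        return AlleleFrequencyPanel(self.snp_map, self.freq_b.copy(), self.freq_a.copy())


# ---------------------------------------------------------------------------
# PED/MAP and BED/BIM/FAM parsing


def _read_map(map_path):
    """Parse a .map body: 4 columns, or 6 with trailing ref/alt alleles.

    The 6-column extension (chrom, id, cM, bp, ref, alt -- the .bim layout)
    pins dosage polarity explicitly; plain 4-column maps leave the reference
    allele to be inferred from the PED (first allele in file order).
    """
    ids, chroms, poss, alleles = [], [], [], []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (4, 6):
                raise PlinkParseError(f"{map_path}: line {ln}: expected 4 or 6 fields")
            chrom_tok, snp = parts[0], parts[1]
            try:
                chrom = int(chrom_tok)
            except ValueError:
                # X/Y/MT style labels mapped to conventional numeric slots
                chrom = {"X": 27, "Y": 28, "XY": 29, "MT": 30}.get(chrom_tok.upper(), -1)
                if chrom < 0:
                    raise PlinkParseError(f"{map_path}: line {ln}: bad chromosome {chrom_tok!r}")
            try:
                pos = int(parts[3])
            except ValueError:
                raise PlinkParseError(f"{map_path}: line {ln}: bad position {parts[3]!r}")
            ids.append(snp)
            chroms.append(chrom)
            poss.append(pos)
            alleles.append((parts[4], parts[5]) if len(parts) == 6 else None)
    snp_map = SnpMap(np.array(ids, dtype=object), np.array(chroms),
                     np.array(poss))
    if all(a is None for a in alleles):
        return snp_map, None
    if any(a is None for a in alleles):
        raise PlinkParseError(f"{map_path}: mixed 4- and 6-column lines")
    return snp_map, np.array(alleles, dtype=object)


def _read_ped(ped_path, n_snps: int):
    sample_ids, breeds, geno_rows = [], [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise PlinkParseError(
                    f"{ped_path}: line {ln}: expected {6 + 2*n_snps} fields, got {len(parts)}")
            breeds.append(parts[0])          # family ID column carries the breed
            sample_ids.append(parts[1])
            geno_rows.append(parts[6:])
    return sample_ids, breeds, geno_rows


def read_plink(genotype_path, map_path=None) -> GenotypeDataset:
    """Read PED/MAP text or a BED/BIM/FAM binary triple.

    For text input pass the .ped and .map paths.  For binary input pass the
    .bed path (the .bim/.fam siblings are found by extension); ``map_path``
    may name the .bim explicitly.  Breed labels are taken from the family-ID
    column.  The reference allele per SNP is the first allele encountered in
    file order (for BED, the A1 allele of the .bim).
    """
    genotype_path = Path(genotype_path)
    if genotype_path.suffix == ".bed":
        return _read_bed_triple(genotype_path, map_path)
    if map_path is None:
        raise ValueError("map_path is required for PED input")
    snp_map, declared = _read_map(map_path)
    L = snp_map.n_snps
    sample_ids, breeds, geno_rows = _read_ped(genotype_path, L)
    n = len(sample_ids)
    dos = np.full((n, L), MISSING)
    alleles = (declared.copy() if declared is not None
               else np.full((L, 2), None, dtype=object))
    for i, row in enumerate(geno_rows):
        a1 = row[0::2]
        a2 = row[1::2]
        for j in range(L):
            x, y = a1[j], a2[j]
            if x == "0" or y == "0":
                continue
            d = 0
            for al in (x, y):
                if alleles[j, 0] is None:
                    alleles[j, 0] = al
                elif alleles[j, 1] is None and al != alleles[j, 0]:
                    alleles[j, 1] = al
                if al == alleles[j, 0]:
                    d += 1
                elif al != alleles[j, 1]:
                    raise PlinkParseError(
                        f"{genotype_path}: sample {sample_ids[i]}: SNP "
                        f"{snp_map.snp_id[j]}: third allele {al!r}")
            dos[i, j] = d
    # monomorphic SNPs never reveal a second allele; keep a placeholder
    for j in range(L):
        if alleles[j, 0] is None:
            alleles[j, 0] = "A"
        if alleles[j, 1] is None:
            alleles[j, 1] = "0"
    return GenotypeDataset(np.array(sample_ids, dtype=object),
                           np.array(breeds, dtype=object), snp_map, dos, alleles)


def write_plink(dataset: GenotypeDataset, genotype_path, map_path) -> None:
    """Write PED plus a 6-column MAP that parse back to an identical dataset.

    The map carries the ref/alt allele characters (.bim layout), so dosage
    polarity survives the round trip even for SNPs whose first written
    genotype is homozygous for the alternate allele.
    """
    sm = dataset.snp_map
    with open(map_path, "w") as fh:
        for j in range(sm.n_snps):
            a1, a2 = dataset.alleles[j]
            fh.write(f"{sm.chromosome[j]}\t{sm.snp_id[j]}\t0\t{sm.position_bp[j]}"
                     f"\t{a1}\t{a2}\n")
    ref = dataset.alleles[:, 0]
    alt = dataset.alleles[:, 1]
    with open(genotype_path, "w") as fh:
        for i in range(dataset.n_samples):
            fields = [str(dataset.breed[i]), str(dataset.sample_id[i]), "0", "0", "0", "-9"]
            row = dataset.dosages[i]
            for j in range(sm.n_snps):
                d = row[j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 2:
                    fields += [str(ref[j]), str(ref[j])]
                elif d == 1:
                    fields += [str(ref[j]), str(alt[j])]
                else:
                    fields += [str(alt[j]), str(alt[j])]
            fh.write(" ".join(fields) + "\n")


_BED_MAGIC = b"\x6c\x1b\x01"   # v1.00, SNP-major


def _read_bed_triple(bed_path: Path, bim_path=None) -> GenotypeDataset:
    bim_path = Path(bim_path) if bim_path else bed_path.with_suffix(".bim")
    fam_path = bed_path.with_suffix(".fam")
    sample_ids, breeds = [], []
    with open(fam_path) as fh:
        for line in fh:
            parts = line.split()
            if parts:
                breeds.append(parts[0])
                sample_ids.append(parts[1])
    ids, chroms, poss, alleles = [], [], [], []
    with open(bim_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise PlinkParseError(f"{bim_path}: line {ln}: expected 6 fields")
            chroms.append(int(parts[0]))
            ids.append(parts[1])
            poss.append(int(parts[3]))
            alleles.append((parts[4], parts[5]))
    snp_map = SnpMap(np.array(ids, dtype=object), np.array(chroms), np.array(poss))
    n, L = len(sample_ids), snp_map.n_snps
    raw = Path(bed_path).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkParseError(f"{bed_path}: bad magic bytes (need v1.00 SNP-major)")
    stride = (n + 3) // 4
    if len(raw) != 3 + stride * L:
        raise PlinkParseError(f"{bed_path}: size mismatch for {n} samples x {L} SNPs")
    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(L, stride)
    # unpack 2-bit codes: 00=hom A1, 01=missing, 10=het, 11=hom A2
    codes = np.empty((L, stride * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    codes = codes[:, :n]
    dos = np.full((L, n), MISSING)
    dos[codes == 0b00] = 2.0   # dosage of A1 = reference
    dos[codes == 0b10] = 1.0
    dos[codes == 0b11] = 0.0
    al = np.array(alleles, dtype=object)
    return GenotypeDataset(np.array(sample_ids, dtype=object),
                           np.array(breeds, dtype=object), snp_map, dos.T, al)


def write_bed(dataset: GenotypeDataset, bed_path) -> None:
    """Write a BED/BIM/FAM triple (v1.00 magic, SNP-major)."""
    bed_path = Path(bed_path)
    sm = dataset.snp_map
    with open(bed_path.with_suffix(".fam"), "w") as fh:
        for i in range(dataset.n_samples):
            fh.write(f"{dataset.breed[i]} {dataset.sample_id[i]} 0 0 0 -9\n")
    with open(bed_path.with_suffix(".bim"), "w") as fh:
        for j in range(sm.n_snps):
            a1, a2 = dataset.alleles[j]
            fh.write(f"{sm.chromosome[j]}\t{sm.snp_id[j]}\t0\t{sm.position_bp[j]}\t{a1}\t{a2}\n")
    n, L = dataset.n_samples, sm.n_snps
    stride = (n + 3) // 4
    codes = np.full((L, stride * 4), 0b01, dtype=np.uint8)   # pad/missing
    d = dataset.dosages.T
    c = np.full_like(d, 0b01, dtype=float)
    c[d == 2] = 0b00
    c[d == 1] = 0b10
    c[d == 0] = 0b11
    codes[:, :n] = c.astype(np.uint8)
    body = np.zeros((L, stride), dtype=np.uint8)
    for k in range(4):
        body |= codes[:, k::4] << (2 * k)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(body.tobytes())


# ---------------------------------------------------------------------------
# Quality control


def qc_filter(dataset: GenotypeDataset, mind: float = 0.1, geno: float = 0.01,
              maf: float = 0.005, autosomes_only: bool = True,
              ) -> tuple[GenotypeDataset, QCReport]:
    """Apply the standard SNP-array quality filters in a fixed order.

    Order: sample missingness (> ``mind`` removed) -> SNP missingness
    (> ``geno``) -> minor allele frequency (< ``maf``, computed among the
    retained samples) -> non-autosomal SNPs.  Threshold semantics follow the
    PLINK commands of the same names.
    """
    if dataset.n_samples == 0 or dataset.n_snps == 0:
        raise ValueError("cannot QC an empty dataset")
    report = QCReport(mind=mind, geno=geno, maf=maf, autosomes_only=autosomes_only)

    miss = np.isnan(dataset.dosages)
    sample_miss = miss.mean(axis=1)
    keep_s = sample_miss <= mind
    for sid in dataset.sample_id[~keep_s]:
        report.removed_samples.append((str(sid), "mind"))
    if not keep_s.any():
        raise EmptyAfterQCError("all samples removed by --mind")

    d = dataset.dosages[keep_s]
    miss = np.isnan(d)
    snp_miss = miss.mean(axis=0)
    n_called = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(d, axis=0) / np.where(n_called > 0, 2 * n_called, 1)
    minor = np.minimum(freq, 1 - freq)

    reason = np.full(dataset.n_snps, "", dtype=object)
    fail_geno = snp_miss > geno
    fail_maf = (~fail_geno) & ((minor < maf) | (n_called == 0))
    chrom = dataset.snp_map.chromosome
    autosomal = np.isin(chrom, list(SHEEP_AUTOSOMES))
    fail_auto = (~fail_geno) & (~fail_maf) & (~autosomal) if autosomes_only \
        else np.zeros(dataset.n_snps, bool)
    reason[fail_geno] = "geno"
    reason[fail_maf] = "maf"
    reason[fail_auto] = "non-autosomal"
    keep_l = reason == ""
    for sid, r in zip(dataset.snp_map.snp_id[~keep_l], reason[~keep_l]):
        report.removed_snps.append((str(sid), str(r)))
    if not keep_l.any():
        raise EmptyAfterQCError("all SNPs removed by QC")
    return dataset.subset(keep_s, keep_l), report


def breed_allele_frequencies(dataset: GenotypeDataset, breed: str) -> np.ndarray:
    """Reference-allele frequency per SNP within one breed.

    frequency = sum(dosages) / (2 * non-missing sample count); SNPs with no
    called genotype in the breed are returned as NaN (flagged undefined).
    """
    mask = dataset.samples_of(breed)
    d = dataset.dosages[mask]
    called = (~np.isnan(d)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(d, axis=0) / (2 * called)
    freq[called == 0] = np.nan
    return freq


def panel_from_breeds(dataset: GenotypeDataset, breed_a: str, breed_b: str,
                      ) -> AlleleFrequencyPanel:
    """Build the two-proxy ancestral frequency panel from labelled cohorts."""
    return AlleleFrequencyPanel(dataset.snp_map,
                                breed_allele_frequencies(dataset, breed_a),
                                breed_allele_frequencies(dataset, breed_b))
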