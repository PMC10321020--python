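"""Domain containers and readers/writers for the formats the pipeline touches.

The pipeline works with three kinds of input: a pedigree (id, sire, dam,
birth year; unknown parents coded "0"), SNP genotypes on the 29 bovine
autosomes (PLINK ped/map text pairs or VCF), and a phenotype table holding
the reproductive-trait records and their fixed-effect factors.  Everything
downstream consumes the containers defined here.

Coordinate conventions: marker positions are 1-based base pairs as in
map/VCF files; genomic intervals are closed ``[start_bp, end_bp]``.
Genotypes are coded as the number of copies of the *second* allele
(ALT in a VCF; in ped/map input the second distinct allele encountered,
ties broken lexicographically), with ``-1`` for missing.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNKNOWN = "0"
MISSING = -1

N_AUTOSOMES = 29


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """Topologically sorted pedigree.

    ``sire`` / ``dam`` hold the integer row index of the parent, or ``-1``
    when the parent is unknown.  Parents always precede offspring.
    """

    ids: list[str]
    sire: np.ndarray          # int32 index into ids, -1 unknown
    dam: np.ndarray
    birth_year: np.ndarray    # float; NaN when missing

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.birth_year = np.asarray(self.birth_year, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate animal ids in pedigree")
        for par in (self.sire, self.dam):
            if par.shape != (n,):
                raise ValueError("parent array length mismatch")
            bad = np.nonzero(par >= np.arange(n))[0]
            if bad.size:
                raise ValueError(
                    f"pedigree not topologically sorted at {self.ids[bad[0]]}"
                )
        self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, animal_id: str) -> int:
        try:
            return self._index[animal_id]
        except KeyError:
            raise KeyError(f"animal {animal_id!r} not in pedigree") from None

    def is_founder(self, i: int) -> bool:
        return self.sire[i] < 0 and self.dam[i] < 0

    @classmethod
    def from_records(
        cls,
        records: list[tuple[str, str, str]] | list[tuple[str, str, str, object]],
    ) -> "Pedigree":
        """Build a pedigree from (id, sire, dam[, birth_year]) records.

        Records may arrive in any order; a topological sort is applied.
        A parent id that never appears as an animal id is added as a
        founder with unknown parents.
        """
        rec = []
        for r in records:
            aid, sid, did = str(r[0]), str(r[1]), str(r[2])
            year = float(r[3]) if len(r) > 3 and r[3] is not None and str(r[3]) not in ("", "NA", "nan") else np.nan
            rec.append((aid, sid, did, year))
        ids_seen = [r[0] for r in rec]
        if len(set(ids_seen)) != len(ids_seen):
            dup = pd.Series(ids_seen).duplicated()
            raise ValueError(f"duplicate animal id {ids_seen[int(np.argmax(dup.values))]!r}")
        known = set(ids_seen)
        # implicit founders for parents never listed as animals
        for _, sid, did, _ in list(rec):
            for pid in (sid, did):
                if pid != UNKNOWN and pid not in known:
                    rec.append((pid, UNKNOWN, UNKNOWN, np.nan))
                    known.add(pid)
        parents = {a: (s, d) for a, s, d, _ in rec}
        years = {a: y for a, s, d, y in rec}
        # Kahn topological sort, deterministic (input order)
        order: list[str] = []
        temp: set[str] = set()
        done: set[str] = set()

        def visit(a: str, stack: tuple[str, ...]) -> None:
            if a in done:
                return
            if a in temp:
                raise ValueError(f"pedigree cycle detected involving {a!r}")
            temp.add(a)
            for p in parents[a]:
                if p != UNKNOWN:
                    visit(p, stack + (a,))
            temp.discard(a)
            done.add(a)
            order.append(a)

        import sys
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * len(rec) + 1000))
        try:
            for a, _, _, _ in rec:
                visit(a, ())
        finally:
            sys.setrecursionlimit(old)
        idx = {a: i for i, a in enumerate(order)}
        sire = np.array([idx[parents[a][0]] if parents[a][0] != UNKNOWN else -1 for a in order])
        dam = np.array([idx[parents[a][1]] if parents[a][1] != UNKNOWN else -1 for a in order])
        year = np.array([years[a] for a in order])
        return cls(order, sire, dam, year)


def read_pedigree(path: str) -> Pedigree:
    """Read a delimited pedigree file (id, sire, dam[, birth_year]; 0=unknown).

    Comma- or whitespace-delimited; a header line is detected and skipped
    when its first field is not reused as a parent anywhere.
    """
    rows: list[tuple[str, ...]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in (line.split(",") if "," in line else line.split())]
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >=3 columns, got {len(parts)}")
            rows.append(tuple(parts[:4]))
    if rows and rows[0][0].lower() in ("id", "animal", "animal_id"):
        rows = rows[1:]
    return Pedigree.from_records(rows)  # type: ignore[arg-type]


def write_pedigree(ped: Pedigree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("id,sire,dam,birth_year\n")
        for i, a in enumerate(ped.ids):
            s = ped.ids[ped.sire[i]] if ped.sire[i] >= 0 else UNKNOWN
            d = ped.ids[ped.dam[i]] if ped.dam[i] >= 0 else UNKNOWN
            y = "" if np.isnan(ped.birth_year[i]) else str(int(ped.birth_year[i]))
            fh.write(f"{a},{s},{d},{y}\n")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """n samples x m biallelic autosomal SNPs, coded by second-allele count.

    ``markers`` is a DataFrame with columns (chrom, pos, a1, a2), sorted by
    (chrom, pos), strictly increasing within chromosome.  ``codes`` holds
    {0, 1, 2} or ``MISSING`` (-1) as int8.
    """

    sample_ids: list[str]
    markers: pd.DataFrame
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        n, m = self.codes.shape
        if n != len(self.sample_ids):
            raise ValueError("codes row count != number of samples")
        if m != len(self.markers):
            raise ValueError("codes column count != number of markers")
        chrom = self.markers["chrom"].to_numpy()
        pos = self.markers["pos"].to_numpy()
        same = chrom[1:] == chrom[:-1]
        if np.any(chrom[1:] < chrom[:-1]) or np.any(same & (pos[1:] <= pos[:-1])):
            raise ValueError("markers not sorted strictly by (chrom, pos)")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def chromosomes(self) -> np.ndarray:
        return np.unique(self.markers["chrom"].to_numpy())

    def chrom_slice(self, chrom: int) -> slice:
        c = self.markers["chrom"].to_numpy()
        lo, hi = np.searchsorted(c, [chrom, chrom + 1])
        return slice(int(lo), int(hi))

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        out = GenotypeMatrix(
            self.sample_ids,
            self.markers.iloc[keep].reset_index(drop=True),
            self.codes[:, keep],
        )
        # simulated matrices carry their founder allele frequencies along
        if hasattr(self, "founder_freqs"):
            out.founder_freqs = np.asarray(self.founder_freqs)[keep]
        return out


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_genotypes(path_ped: str, path_map: str) -> GenotypeMatrix:
    """Read a PLINK ped/map text pair.

    The second allele of a marker is the second distinct allele seen
    scanning samples in order, ties broken lexicographically when both
    appear first in the same genotype; "0" denotes a missing allele.
    Non-autosomal markers (chrom outside 1..29) are dropped.
    """
    mrk = pd.read_csv(
        path_map, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos"], dtype={"chrom": str},
    )
    m = len(mrk)
    samples: list[str] = []
    allele_pairs: list[list[tuple[str, str]]] = []
    with _open_text(path_ped) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{path_ped}:{ln}: expected {6 + 2 * m} fields "
                    f"(6 + 2x{m} markers), got {len(parts)}"
                )
            samples.append(parts[1])
            allele_pairs.append(
                [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(m)]
            )
    n = len(samples)
    # determine the two alleles per marker
    codes = np.full((n, m), MISSING, dtype=np.int8)
    a1_l, a2_l = [], []
    for j in range(m):
        seen: list[str] = []
        for i in range(n):
            # within one genotype new alleles are taken lexicographically,
            # across genotypes in encounter order
            new = sorted(
                {a for a in allele_pairs[i][j] if a != "0" and a not in seen}
            )
            seen.extend(new)
        if len(seen) > 2:
            raise ValueError(f"marker {mrk['snp_id'][j]} has >2 alleles")
        a1 = seen[0] if seen else "0"
        a2 = seen[1] if len(seen) == 2 else "0"
        a1_l.append(a1)
        a2_l.append(a2)
        for i in range(n):
            x, y = allele_pairs[i][j]
            if x == "0" or y == "0":
                continue
            codes[i, j] = (x == a2) + (y == a2)
    mrk["a1"], mrk["a2"] = a1_l, a2_l
    return _finalise_matrix(samples, mrk, codes)


def _finalise_matrix(samples, mrk: pd.DataFrame, codes: np.ndarray) -> GenotypeMatrix:
    chrom_num = pd.to_numeric(mrk["chrom"], errors="coerce")
    auto = chrom_num.between(1, N_AUTOSOMES) & (chrom_num == chrom_num.astype("Int64"))
    dropped = int((~auto).sum())
    if dropped:
        logger.info("dropped %d non-autosomal markers", dropped)
    mrk = mrk.loc[auto.to_numpy()].copy()
    mrk["chrom"] = chrom_num[auto].astype(int).to_numpy()
    codes = codes[:, auto.to_numpy()]
    order = np.lexsort((mrk["pos"].to_numpy(), mrk["chrom"].to_numpy()))
    mrk = mrk.iloc[order].reset_index(drop=True)
    codes = codes[:, order]
    cols = ["chrom", "pos", "a1", "a2"]
    if "snp_id" in mrk.columns:
        cols = ["chrom", "pos", "a1", "a2", "snp_id"]
    return GenotypeMatrix(list(samples), mrk[cols], codes)


def read_vcf(path: str) -> GenotypeMatrix:
    """Read genotypes from a VCF (uncompressed or gzip); ALT is the second allele.

    Multi-allelic sites are rejected; non-autosomal records are dropped.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    chroms, poss, a1s, a2s, rows = [], [], [], [], []
    for var in vcf:
        if len(var.ALT) > 1:
            raise ValueError(f"multi-allelic site at {var.CHROM}:{var.POS}")
        chroms.append(var.CHROM.removeprefix("chr"))
        poss.append(var.POS)
        a1s.append(var.REF)
        a2s.append(var.ALT[0] if var.ALT else ".")
        gt = var.gt_types.astype(np.int8)  # 0,1,2 alt copies; 3 unknown
        gt[gt == 3] = MISSING
        rows.append(gt)
    vcf.close()
    mrk = pd.DataFrame({"chrom": chroms, "pos": poss, "a1": a1s, "a2": a2s})
    codes = (
        np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return _finalise_matrix(samples, mrk, codes)


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write a minimal GT-only VCF (gzip when path ends in .gz)."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    fh = gzip.open(path, "wt") if str(path).endswith(".gz") else open(path, "w")
    with fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in g.chromosomes():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.sample_ids) + "\n")
        mk = g.markers
        for j in range(g.n_markers):
            ref = mk["a1"].iat[j] if str(mk["a1"].iat[j]) not in ("0", ".") else "A"
            alt = mk["a2"].iat[j] if str(mk["a2"].iat[j]) not in ("0", ".") else "B"
            row = "\t".join(gt_str[int(x)] for x in g.codes[:, j])
            fh.write(
                f"{mk['chrom'].iat[j]}\t{mk['pos'].iat[j]}\tsnp{j}\t{ref}\t{alt}"
                f"\t.\t.\t.\tGT\t{row}\n"
            )


def write_plink(g: GenotypeMatrix, prefix: str) -> None:
    """Write a PLINK ped/map text pair to ``prefix + '.ped'/'.map'``."""
    mk = g.markers
    with open(prefix + ".map", "w") as fh:
        for j in range(g.n_markers):
            sid = mk["snp_id"].iat[j] if "snp_id" in mk.columns else f"snp{j}"
            fh.write(f"{mk['chrom'].iat[j]}\t{sid}\t0\t{mk['pos'].iat[j]}\n")
    a1 = mk["a1"].astype(str).to_numpy()
    a2 = mk["a2"].astype(str).to_numpy()
    with open(prefix + ".ped", "w") as fh:
        for i, s in enumerate(g.sample_ids):
            fields = [s, s, "0", "0", "0", "-9"]
            for j in range(g.n_markers):
                x = int(g.codes[i, j])
                if x == MISSING:
                    fields += ["0", "0"]
                elif x == 0:
                    fields += [a1[j], a1[j]]
                elif x == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

#: canonical phenotype-table columns
PHENO_COLUMNS = ["id", "trait", "value", "sex", "month", "herd_year", "afc"]


def read_phenotypes(path: str) -> pd.DataFrame:
    """Read a phenotype CSV with columns id,trait,value,sex,month,herd_year,afc.

    ``trait`` names one of AFC (age at first calving, days), CD (calving
    difficulty score 1-5) or GL (gestation length, days); ``afc`` is the
    per-cow AFC covariate used in the CD/GL models.
    """
    df = pd.read_csv(path, dtype={"id": str, "sex": str, "herd_year": str})
    missing = [c for c in PHENO_COLUMNS if c not in df.columns and c != "afc"]
    if missing:
        raise ValueError(f"phenotype file missing columns: {missing}")
    return df


def write_table(rows, path: str, columns: list[str] | None = None) -> None:
    """Write records as TSV with header; floats printed to 6 significant digits."""
    df = pd.DataFrame(rows, columns=columns) if not isinstance(rows, pd.DataFrame) else rows
    if columns is not None and not isinstance(rows, pd.DataFrame):
        df = df.reindex(columns=columns)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
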