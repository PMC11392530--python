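"""Readers and writers for the standard interchange formats.

Internal coordinates are 0-based half-open everywhere; VCF (1-based) and BED
(0-based half-open) conventions are translated at this boundary.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from .methylome import MethylomeMatrix

__all__ = [
    "read_variants",
    "write_vcf",
    "read_methylome",
    "write_methylome_tsv",
    "read_bed",
    "write_bed",
]

_NUC = np.array(list("ACGT"))
_NUC_INDEX = {b: i for i, b in enumerate("ACGT")}


def read_variants(vcf_path, samples: Optional[Sequence[str]] = None,
                  collapse_diploid: bool = True):
    """Read nucleotide states from a VCF.

    Haploid genotypes are taken as-is; homozygous diploid genotypes are
    collapsed to one haplotype when ``collapse_diploid`` (heterozygous and
    "./." calls become missing), mirroring the haploid treatment of highly
    selfing samples.  Multi-allelic records are retained (finite-site
    model).  Returns (positions 0-based, state matrix with A/C/G/T as
    0..3 and -1 missing, sample names).
    """
    from cyvcf2 import VCF
    vcf = VCF(str(vcf_path))
    names = list(vcf.samples)
    if samples is not None:
        missing = [s for s in samples if s not in names]
        if missing:
            raise ValueError(f"unknown sample(s): {missing}")
        idx = [names.index(s) for s in samples]
        names = list(samples)
    else:
        idx = list(range(len(names)))
    positions: List[int] = []
    rows: List[np.ndarray] = []
    for rec_no, v in enumerate(vcf, start=1):
        try:
            alleles = [v.REF] + list(v.ALT)
            codes = []
            for a in alleles:
                codes.append(_NUC_INDEX.get(a.upper(), -1) if a else -1)
            gts = v.genotypes
            out = np.full(len(idx), -1, dtype=np.int8)
            for col, k in enumerate(idx):
                g = gts[k]
                calls = [a for a in g[:-1] if a is not None]
                if len(calls) == 0 or any(c < 0 for c in calls):
                    continue
                if len(calls) == 1:
                    out[col] = codes[calls[0]]
                elif collapse_diploid:
                    out[col] = codes[calls[0]] if calls[0] == calls[1] else -1
                else:
                    out[col] = codes[calls[0]]
            positions.append(v.POS - 1)  # VCF is 1-based
            rows.append(out)
        except (IndexError, TypeError, KeyError) as exc:
            raise ValueError(f"malformed VCF record #{rec_no} "
                             f"at {v.CHROM}:{v.POS}: {exc}") from exc
    pos = np.asarray(positions, dtype=np.int64)
    states = (np.vstack(rows) if rows
              else np.empty((0, len(idx)), dtype=np.int8))
    order = np.argsort(pos, kind="stable")
    return pos[order], states[order], names


def write_vcf(positions, states, path, chrom: str = "1",
              sample_prefix: str = "hap"):
    """Write nucleotide states (0..3 = A/C/G/T, -1 missing) as a simple VCF."""
    positions = np.asarray(positions)
    states = np.asarray(states)
    n = states.shape[1]
    names = [f"{sample_prefix}{k + 1}" for k in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for p, row in zip(positions, states):
            valid = row[row >= 0]
            if len(valid) == 0:
                continue
            ref = int(valid[0])
            alts = [a for a in np.unique(valid) if a != ref]
            alleles = [ref] + [int(a) for a in alts]
            amap = {a: k for k, a in enumerate(alleles)}
            gts = [("." if s < 0 else str(amap[int(s)])) for s in row]
            alt_str = ",".join(_NUC[a] for a in alts) if alts else "."
            fh.write(f"{chrom}\t{p + 1}\t.\t{_NUC[ref]}\t{alt_str}\t.\tPASS\t"
                     f".\tGT\t" + "\t".join(gts) + "\n")


def read_bed(path) -> np.ndarray:
    """(m, 2) array of 0-based half-open intervals from a BED file."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((int(parts[1]), int(parts[2])))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def write_bed(regions, path, chrom: str = "1"):
    with open(path, "w") as fh:
        for s, e in np.asarray(regions):
            fh.write(f"{chrom}\t{int(s)}\t{int(e)}\n")


_STATUS = {"M": 1, "U": 0, ".": -1}
_STATUS_INV = {1: "M", 0: "U", -1: "."}


def read_methylome(tsv_path, bed_path=None, sequence_length: Optional[int] = None,
                   context: str = "CG") -> MethylomeMatrix:
    """Read a per-site methylation-state table.

    Expected columns: CHROM, POS (1-based), CONTEXT, then one status column
    per sample with values M / U / "." (missing).  Only records in the
    requested context and, when a BED of genic regions is given, inside
    those intervals are kept.
    """
    import pandas as pd
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    required = {"CHROM", "POS", "CONTEXT"}
    if not required.issubset(df.columns):
        raise ValueError(f"methylome table needs columns {sorted(required)}")
    samples = [c for c in df.columns if c not in required]
    df = df[df["CONTEXT"] == context]
    pos = df["POS"].astype(np.int64).to_numpy() - 1  # to 0-based
    regions = None
    if bed_path is not None:
        regions = read_bed(bed_path)
        keep = np.zeros(len(pos), dtype=bool)
        for s, e in regions:
            keep |= (pos >= s) & (pos < e)
        df = df[keep]
        pos = pos[keep]
    states = np.full((len(pos), len(samples)), -1, dtype=np.int8)
    for k, s in enumerate(samples):
        col = df[s].to_numpy()
        bad = ~np.isin(col, list(_STATUS))
        if bad.any():
            raise ValueError(f"status outside alphabet M/U/. for sample {s!r}: "
                             f"{col[bad][:3]}")
        states[:, k] = [_STATUS[v] for v in col]
    L = sequence_length or (int(pos.max()) + 1 if len(pos) else 0)
    return MethylomeMatrix(pos, states, L, genic_regions=regions,
                           samples=samples)


def write_methylome_tsv(methylome: MethylomeMatrix, path, chrom: str = "1",
                        context: str = "CG"):
    import pandas as pd
    n = methylome.n_haplotypes
    names = methylome.samples or [f"hap{k + 1}" for k in range(n)]
    df = pd.DataFrame({"CHROM": chrom, "POS": methylome.positions + 1,
                       "CONTEXT": context})
    for k, s in enumerate(names):
        df[s] = [_STATUS_INV[int(v)] for v in methylome.states[:, k]]
    df.to_csv(path, sep="\t", index=False)
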