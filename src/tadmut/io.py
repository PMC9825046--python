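"""Plain-text I/O for the formats the pipeline consumes and emits.

Contact maps travel as COO triplet text (chrom, bin_i, bin_j, count; upper
triangle only) next to a two-column chrom.sizes file.  Genes are BED6,
somatic SNVs a minimal VCF, CNV segments a SEG-like TSV, SVs BEDPE with a
class column, expression a TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BinnedGenome
from .hic import ContactMap

VCF_COLUMNS = ["CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]


# ---------------------------------------------------------------- contact maps


def write_contact_map(cmap: ContactMap, path: str | Path) -> None:
    """Write the upper triangle of every chromosome as triplet text."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#chrom\tbin_i\tbin_j\tcount\n")
        for chrom in cmap.genome.chrom_names:
            m = cmap.matrices[chrom]
            iu, ju = np.nonzero(np.triu(m))
            for i, j in zip(iu, ju):
                v = m[i, j]
                v_str = str(int(v)) if float(v).is_integer() else repr(float(v))
                fh.write(f"{chrom}\t{i}\t{j}\t{v_str}\n")


def read_contact_map(path: str | Path, genome: BinnedGenome) -> ContactMap:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["chrom", "bin_i", "bin_j", "count"],
        dtype={"chrom": str},
    )
    matrices = {}
    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom)
        m = np.zeros((n, n))
        sub = df[df["chrom"] == chrom]
        i = sub["bin_i"].to_numpy(int)
        j = sub["bin_j"].to_numpy(int)
        v = sub["count"].to_numpy(float)
        m[i, j] = v
        m[j, i] = v
        matrices[chrom] = m
    return ContactMap(genome, matrices)


def write_chrom_sizes(genome: BinnedGenome, path: str | Path) -> None:
    Path(path).write_text(genome.to_chrom_sizes_text())


def read_chrom_sizes(path: str | Path, bin_size: int = 50_000) -> BinnedGenome:
    return BinnedGenome.from_chrom_sizes_text(Path(path).read_text(), bin_size)


# ------------------------------------------------------------------- intervals


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write a BED6 file from columns chrom/start/end[/name/score/strand]."""
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", "+")):
        if col not in out:
            out[col] = default
    out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path: str | Path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype={0: str})
    df.columns = names[: df.shape[1]]
    return df


# ------------------------------------------------------------------- mutations


def write_vcf(muts: pd.DataFrame, path: str | Path) -> None:
    """Minimal VCF: fixed 8 columns, gene carried as an INFO GENE= tag."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#" + "\t".join(VCF_COLUMNS) + "\n")
        for _, r in muts.iterrows():
            info = f"GENE={r['gene']}" if r.get("gene") and pd.notna(r["gene"]) else "."
            fh.write(
                f"{r['chrom']}\t{r['pos']}\t{r.get('id', '.')}\t{r['ref']}\t{r['alt']}\t"
                f"{r.get('qual', '.')}\t{r['filter']}\t{info}\n"
            )


def read_vcf(path: str | Path) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        gene = None
        for tag in f[7].split(";"):
            if tag.startswith("GENE="):
                gene = tag[5:]
        rows.append(
            {
                "chrom": f[0],
                "pos": int(f[1]),
                "id": f[2],
                "ref": f[3],
                "alt": f[4],
                "qual": f[5],
                "filter": f[6],
                "gene": gene,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt", "qual", "filter", "gene"])


# ----------------------------------------------------------------- CNV and SV


def write_seg(segments: pd.DataFrame, path: str | Path) -> None:
    segments[["chrom", "start", "end", "cn"]].to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_bedpe(svs: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "sv_class"]
    svs[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bedpe(path: str | Path) -> pd.DataFrame:
    names = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "sv_class"]
    return pd.read_csv(path, sep="\t", header=None, names=names, dtype={0: str, 3: str})


# ----------------------------------------------------------------- expression


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
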