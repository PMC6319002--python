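"""Plain-text readers/writers for the pipeline's tabular artifacts.

Formats: dosage TSV (animals x markers), marker map TSV, counts TSV (genes x
samples), gene annotation BED (0-based half-open on disk, converted to the
package's 1-based closed coordinates on read), phenotype/covariate CSV and
truth TSVs.  All tables are UTF-8 with a header row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import CountMatrix, GenotypeData

__all__ = [
    "write_dosages", "read_dosages",
    "write_marker_map", "read_marker_map",
    "write_counts", "read_counts",
    "write_genes_bed", "read_genes_bed",
    "write_phenotypes", "read_phenotypes",
    "write_dataset",
]


def write_dosages(path, M: np.ndarray, animal_ids, marker_ids) -> None:
    df = pd.DataFrame(np.asarray(M, dtype=int), columns=list(marker_ids))
    df.insert(0, "animal", list(animal_ids))
    df.to_csv(path, sep="\t", index=False)


def read_dosages(path):
    df = pd.read_csv(path, sep="\t")
    animals = df["animal"].tolist()
    M = df.drop(columns="animal").to_numpy(dtype=float)
    markers = [c for c in df.columns if c != "animal"]
    return M, animals, markers


def write_marker_map(path, marker_map: pd.DataFrame) -> None:
    marker_map.to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_counts(path, cm: CountMatrix) -> None:
    df = pd.DataFrame(cm.counts, columns=[str(s) for s in cm.samples])
    df.insert(0, "gene", cm.genes["gene"].tolist())
    df.to_csv(path, sep="\t", index=False)


def read_counts(path, genes: pd.DataFrame) -> CountMatrix:
    df = pd.read_csv(path, sep="\t")
    samples = [c for c in df.columns if c != "gene"]
    counts = df[samples].to_numpy(dtype=np.int64)
    annot = genes.set_index("gene").loc[df["gene"]].reset_index()
    return CountMatrix(counts=counts, genes=annot, samples=samples)


def write_genes_bed(path, genes: pd.DataFrame) -> None:
    """1-based closed spans on the frame -> 0-based half-open BED rows."""
    bed = pd.DataFrame({
        "chrom": genes["chrom"],
        "start": genes["start"].astype(int) - 1,
        "end": genes["end"].astype(int),
        "gene": genes["gene"],
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_genes_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "gene"])
    return pd.DataFrame({
        "gene": bed["gene"],
        "chrom": bed["chrom"],
        "start": bed["start"].astype(int) + 1,
        "end": bed["end"].astype(int),
    })


def write_phenotypes(path, phen: pd.DataFrame) -> None:
    phen.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_dataset(outdir, geno: GenotypeData, cm: CountMatrix,
                  phen: pd.DataFrame, truth=None) -> None:
    """Write the full simulated dataset as the pipeline's text artifacts."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    kept = geno.kept_map
    write_dosages(out / "dosages.tsv", geno.M, geno.animal_ids or
                  list(range(geno.M.shape[0])), kept["marker"])
    write_marker_map(out / "marker_map.tsv", geno.map)
    write_counts(out / "counts.tsv", cm)
    write_genes_bed(out / "genes.bed", cm.genes)
    write_phenotypes(out / "phenotypes.csv", phen)
    if truth is not None:
        truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
        truth.phenotypes.to_csv(out / "truth_phenotypes.tsv", sep="\t", index=False)
        truth.pairs.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)


def read_dataset(indir):
    """Load a dataset previously written by :func:`write_dataset`."""
    ind = Path(indir)
    mp = read_marker_map(ind / "marker_map.tsv")
    M, animals, markers = read_dosages(ind / "dosages.tsv")
    kept_ids = mp.loc[mp["status"] == "kept", "marker"].tolist()
    if markers != kept_ids:
        order = [markers.index(m) for m in kept_ids]
        M = M[:, order]
    p = M.mean(axis=0) / 2.0
    geno = GenotypeData(M=M, p=p, map=mp, animal_ids=animals)
    genes = read_genes_bed(ind / "genes.bed")
    cm = read_counts(ind / "counts.tsv", genes)
    phen = read_phenotypes(ind / "phenotypes.csv")
    return geno, cm, phen
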