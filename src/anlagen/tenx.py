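"""Reading and writing 10x-style sparse count directories.

A directory holds ``matrix.mtx`` (MatrixMarket integer coordinate, genes as
rows), ``features.tsv`` (gene id <tab> gene name) and ``barcodes.tsv`` (one
barcode per line), all uncompressed. The writer/reader pair round-trips a
:class:`~anlagen.containers.CountMatrix` bit-exactly.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix

MATRIX_FILE = "matrix.mtx"
FEATURES_FILE = "features.tsv"
BARCODES_FILE = "barcodes.tsv"


def write_tenx(matrix: CountMatrix, directory) -> Path:
    """Write `matrix` as a 10x-style directory; returns the directory path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if len(set(matrix.barcodes)) != len(matrix.barcodes):
        raise ValueError("duplicate barcodes")
    scipy.io.mmwrite(
        os.fspath(directory / MATRIX_FILE),
        sp.coo_matrix(matrix.counts),
        field="integer",
    )
    with open(directory / FEATURES_FILE, "w") as fh:
        for g in matrix.gene_names:
            fh.write(f"{g}\t{g}\n")
    with open(directory / BARCODES_FILE, "w") as fh:
        for b in matrix.barcodes:
            fh.write(f"{b}\n")
    return directory


def read_tenx(directory, replicate: str = "r1", day: int = 0) -> CountMatrix:
    """Read a 10x-style directory written by :func:`write_tenx`."""
    directory = Path(directory)
    counts = scipy.io.mmread(os.fspath(directory / MATRIX_FILE))
    genes = []
    with open(directory / FEATURES_FILE) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                genes.append(line.split("\t")[1] if "\t" in line else line)
    barcodes = []
    with open(directory / BARCODES_FILE) as fh:
        for line in fh:
            line = line.strip()
            if line:
                barcodes.append(line)
    counts = sp.csr_matrix(counts, shape=(len(genes), len(barcodes)))
    return CountMatrix(
        counts.astype(np.int64),
        np.asarray(genes, dtype=object),
        np.asarray(barcodes, dtype=object),
        replicate=replicate,
        day=day,
    )
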