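"""Readers and writers for the enrichment-tool file formats.

GMT (gene sets), CLS (categorical phenotype labels), RNK (ranked list) and
the two-column directional-signature TSV.  These formats are line-oriented
and deliberately simple; parse failures name the file and line.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ParseError
from .gsea import GeneSet, RankedList
from .overlap import DirectionalSignature


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file: name <tab> description <tab> member genes..."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT rows need name, description "
                    f"and at least one gene (got {len(fields)} fields)"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if name in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            if len(set(genes)) != len(genes):
                raise ParseError(f"{path}: line {lineno}: duplicate genes in set {name!r}")
            seen.add(name)
            sets.append(GeneSet(name=name, genes=tuple(genes), description=description))
    if not sets:
        raise ParseError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description or "na", *s.genes]) + "\n")


def read_cls(path) -> list[str]:
    """Read a 3-line categorical CLS file; returns per-sample labels."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) != 3:
        raise ParseError(f"{path}: CLS needs exactly 3 non-empty lines, got {len(lines)}")
    header = lines[0].split()
    if len(header) != 3:
        raise ParseError(f"{path}: line 1: expected '<n> <k> 1'")
    n_samples, n_classes = int(header[0]), int(header[1])
    if not lines[1].startswith("#"):
        raise ParseError(f"{path}: line 2: class-name line must start with '#'")
    class_names = lines[1][1:].split()
    if len(class_names) != n_classes:
        raise ParseError(
            f"{path}: line 2: {len(class_names)} class names, header says {n_classes}"
        )
    labels = lines[2].split()
    if len(labels) != n_samples:
        raise ParseError(f"{path}: line 3: {len(labels)} labels, header says {n_samples}")
    # labels may be class names or 0-based class indices
    if set(labels) <= set(class_names):
        return labels
    try:
        return [class_names[int(v)] for v in labels]
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}: line 3: labels match neither names nor indices") from exc


def write_cls(labels: list[str], path) -> None:
    classes = list(dict.fromkeys(labels))  # order of first appearance
    with open(path, "w") as fh:
        fh.write(f"{len(labels)} {len(classes)} 1\n")
        fh.write("# " + " ".join(classes) + "\n")
        fh.write(" ".join(labels) + "\n")


def read_signature_tsv(path) -> DirectionalSignature:
    """Read a directional signature: gene <tab> up|down per line."""
    entries: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[:2] == ["gene", "direction"]:
                continue
            if len(fields) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 'gene<TAB>direction'")
            gene, direction = fields
            if direction not in ("up", "down"):
                raise ParseError(
                    f"{path}: line {lineno}: direction must be up or down, got {direction!r}"
                )
            if gene in entries:
                raise ParseError(f"{path}: line {lineno}: duplicate gene {gene!r}")
            entries[gene] = direction
    if not entries:
        raise ParseError(f"{path}: empty signature")
    return DirectionalSignature(entries=entries)


def write_signature_tsv(signature: DirectionalSignature, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tdirection\n")
        for gene, direction in signature.entries.items():
            fh.write(f"{gene}\t{direction}\n")


def write_rnk(ranked: RankedList, path) -> None:
    """Export a ranked list in the two-column RNK format."""
    pd.DataFrame({"gene": ranked.genes, "score": ranked.scores}).to_csv(
        path, sep="\t", header=False, index=False, float_format="%.8g"
    )


def read_rnk(path) -> RankedList:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
    if df["gene"].duplicated().any():
        raise ParseError(f"{path}: duplicate genes in RNK file")
    order = np.lexsort((df["gene"].to_numpy(dtype=object), -df["score"].to_numpy()))
    return RankedList(
        genes=df["gene"].to_numpy(dtype=object)[order],
        scores=df["score"].to_numpy(dtype=float)[order],
    )
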