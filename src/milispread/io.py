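"""Readers/writers for the plain-text interchange formats used by the pipeline."""

from __future__ import annotations

from typing import Dict, List, Sequence


def read_gmt(path) -> Dict[str, List[str]]:
    """Parse a GMT gene-set file: set name, description, then member genes."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(gene_sets: Dict[str, Sequence[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for set_id, genes in gene_sets.items():
            fh.write("\t".join([set_id, description, *genes]) + "\n")
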