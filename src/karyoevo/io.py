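"""Plain-text readers/writers: gene-order TSV, event-log JSON, newick tree
sets, FASTA alignments, Ks tables, and collinearity TSV in the MCScanX-like
block format (a header line per block, one anchor pair per line)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .genome import EvolutionEvent
from .synteny import CollinearBlock

__all__ = [
    "write_event_log",
    "read_event_log",
    "write_trees",
    "read_trees",
    "write_fasta",
    "write_blocks",
    "read_blocks",
    "write_ks_table",
    "read_ks_table",
]


def write_event_log(log: dict[str, list[EvolutionEvent]], path) -> None:
    payload = {
        branch: [dataclasses.asdict(e) for e in events] for branch, events in log.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_event_log(path) -> dict[str, list[EvolutionEvent]]:
    payload = json.loads(Path(path).read_text())
    return {
        branch: [EvolutionEvent(**e) for e in events] for branch, events in payload.items()
    }


def write_trees(trees: Sequence[str], path) -> None:
    Path(path).write_text("\n".join(t.strip() for t in trees) + "\n")


def read_trees(path) -> list[str]:
    return [line for line in Path(path).read_text().splitlines() if line.strip()]


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_blocks(blocks: Sequence[CollinearBlock], path) -> None:
    with open(path, "w") as fh:
        for blk in blocks:
            fh.write(
                f"# block {blk.block_id}\t{blk.species_a}:{blk.chrom_a}\t"
                f"{blk.species_b}:{blk.chrom_b}\t"
                f"orientation={'+' if blk.orientation > 0 else '-'}\t"
                f"score={blk.score}\n"
            )
            for ia, ib, ga, gb in blk.anchors:
                fh.write(f"{ga}\t{gb}\t{ia}\t{ib}\n")


def read_blocks(path) -> list[CollinearBlock]:
    blocks: list[CollinearBlock] = []
    current = None
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("# block"):
            parts = line.split("\t")
            bid = int(parts[0].split()[-1])
            sa, ca = parts[1].split(":", 1)
            sb, cb = parts[2].split(":", 1)
            orient = 1 if parts[3].endswith("+") else -1
            current = CollinearBlock(
                species_a=sa, species_b=sb, chrom_a=ca, chrom_b=cb,
                orientation=orient, anchors=[], block_id=bid,
            )
            blocks.append(current)
        else:
            ga, gb, ia, ib = line.split("\t")
            current.anchors.append((int(ia), int(ib), ga, gb))
    return blocks


def write_ks_table(ks: pd.DataFrame, path) -> None:
    ks.to_csv(path, sep="\t", index=False)


def read_ks_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
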