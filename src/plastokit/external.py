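"""Wrappers around external command-line tools.

Whole-genome multiple alignment goes through MAFFT when it is on PATH: the
pipeline's own progressive aligner is meant for locus-sized sequences and
does not scale to full plastomes.  Callers fall back to the internal aligner
when MAFFT is unavailable.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path


def have_mafft() -> bool:
    return shutil.which("mafft") is not None


def mafft_align(names: list[str], seqs: list[str]) -> list[str]:
    """Align sequences with MAFFT (--auto --quiet); returns aligned rows in
    input order.  Raises ``RuntimeError`` if MAFFT is not installed."""
    if not have_mafft():
        raise RuntimeError("mafft is not on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.fasta"
        with open(fasta, "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f">s{i}\n{s}\n")
        proc = subprocess.run(
            ["mafft", "--auto", "--quiet", str(fasta)],
            capture_output=True,
            text=True,
            check=True,
        )
    rows: dict[str, list[str]] = {}
    current = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            current = line[1:].strip()
            rows[current] = []
        elif current is not None:
            rows[current].append(line.strip())
    return ["".join(rows[f"s{i}"]).upper() for i in range(len(seqs))]
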