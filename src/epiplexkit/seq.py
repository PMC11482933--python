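"""Small sequence helpers (reverse complement, FASTA/FASTQ writing)."""

from __future__ import annotations

import gzip

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def write_fasta(records: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


class FastqWriter:
    """Minimal gzipped 4-line FASTQ writer (Phred+33)."""

    def __init__(self, path: str):
        self._fh = gzip.open(path, "wt")

    def write(self, name: str, seq: str, qual: str) -> None:
        self._fh.write(f"@{name}\n{seq}\n+\n{qual}\n")

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
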