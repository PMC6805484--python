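"""Genome sequence access (in-memory dict or indexed FASTA via pyfaidx)."""

from __future__ import annotations

from typing import Mapping

from pyfaidx import Fasta

from .errors import InputError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeStore:
    """Uniform accessor over a ``{chrom: sequence}`` dict or a FASTA path.

    All coordinates 0-based half-open; minus-strand fetches return the
    reverse complement (i.e. the transcript-orientation sequence).
    """

    def __init__(self, source: Mapping[str, str] | str):
        if isinstance(source, str):
            try:
                self._fasta = Fasta(source, as_raw=True, sequence_always_upper=True)
            except Exception as exc:  # pragma: no cover - passthrough detail
                raise InputError(f"cannot open FASTA {source}: {exc}") from exc
            self._dict = None
        else:
            self._dict = {k: str(v).upper() for k, v in source.items()}
            self._fasta = None

    @property
    def contigs(self) -> list[str]:
        if self._dict is not None:
            return list(self._dict)
        return list(self._fasta.keys())

    def length(self, chrom: str) -> int:
        if self._dict is not None:
            return len(self._dict[chrom])
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence for [start, end); clipped at contig bounds."""
        start = max(0, start)
        end = min(self.length(chrom), end)
        if end <= start:
            return ""
        if self._dict is not None:
            seq = self._dict[chrom][start:end]
        else:
            seq = str(self._fasta[chrom][start:end]).upper()
        return revcomp(seq) if strand == "-" else seq


def write_fasta(genome: Mapping[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
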