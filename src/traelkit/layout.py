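"""Genome layout: chromosome names and lengths.

A :class:`GenomeLayout` is the minimal coordinate frame the rest of the
package works in — an ordered mapping of chromosome name to length in base
pairs, read from and written to the standard two-column ``chrom.sizes`` TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome name → length (bp) mapping.

    Parameters
    ----------
    chromosomes
        Mapping of chromosome name to length in base pairs. Names must be
        unique (enforced by the dict) and lengths strictly positive.
    """

    chromosomes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.chromosomes.items():
            if not name:
                raise ValueError("chromosome name must be non-empty")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __iter__(self) -> Iterator[str]:
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def length(self, name: str) -> int:
        return self.chromosomes[name]

    @property
    def total_length(self) -> int:
        return sum(self.chromosomes.values())

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column ``<name>\\t<length>`` TSV (UCSC chrom.sizes)."""
        chroms: dict[str, int] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            name = parts[0]
            if name in chroms:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            chroms[name] = int(parts[1])
        return cls(chroms)

    def to_chrom_sizes(self, path: str | Path) -> None:
        lines = [f"{name}\t{length}" for name, length in self.chromosomes.items()]
        Path(path).write_text("\n".join(lines) + "\n")


def uniform_layout(n_chromosomes: int = 2, length: int = 500_000) -> GenomeLayout:
    """Desk-scale layout: ``n`` equal chromosomes named chr01, chr02, ..."""
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    return GenomeLayout({f"chr{i + 1:02d}": length for i in range(n_chromosomes)})
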