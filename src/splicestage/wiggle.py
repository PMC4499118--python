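"""Minimal signed variableStep wiggle writer/reader.

Used for the split-gap peak tracks: one line per peak position (1-based),
value = +magnitude for split starts and -magnitude for split ends.
"""

from __future__ import annotations

from pathlib import Path


def write_wiggle(entries: dict[int, int], chrom: str, path: str | Path,
                 span: int = 1) -> None:
    """Write {1-based position: signed value} as a variableStep track."""
    lines = [f"variableStep chrom={chrom} span={span}"]
    for pos in sorted(entries):
        lines.append(f"{pos}\t{entries[pos]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_wiggle(path: str | Path) -> tuple[str, dict[int, int]]:
    """Read a variableStep track back into (chrom, {position: value})."""
    chrom = ""
    entries: dict[int, int] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("track"):
            continue
        if line.startswith(("variableStep", "fixedStep")):
            for field in line.split():
                if field.startswith("chrom="):
                    chrom = field.split("=", 1)[1]
            continue
        pos, value = line.split()
        entries[int(pos)] = int(value)
    return chrom, entries
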