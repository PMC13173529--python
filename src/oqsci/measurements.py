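"""Computational-basis measurement sets and their plain-text interchange form.

A measurement set is a multiset of 2M-qubit bitstrings with shot counts.
Bitstrings are written qubit-0-first: the leftmost character is spin
orbital 0 (alpha spatial orbital 0 under the blocked ordering).

Text format: a header line ``# qubits=2M shots=N`` (optionally followed by
further ``key=value`` provenance tokens), then one record per line,
``<bitstring> <count>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["MeasurementSet", "write_measurements", "read_measurements"]


@dataclass
class MeasurementSet:
    """Multiset of equal-length measurement bitstrings."""

    counts: dict[str, int]
    n_qubits: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for b in self.counts:
            if len(b) != self.n_qubits or set(b) - {"0", "1"}:
                raise ValueError(f"malformed bitstring {b!r}")

    @property
    def n_shots(self) -> int:
        return sum(self.counts.values())

    def merge(self, other: "MeasurementSet") -> "MeasurementSet":
        if other.n_qubits != self.n_qubits:
            raise ValueError("qubit counts differ")
        merged = dict(self.counts)
        for b, c in other.counts.items():
            merged[b] = merged.get(b, 0) + c
        return MeasurementSet(merged, self.n_qubits, dict(self.provenance))


def write_measurements(ms: MeasurementSet, path: str | Path) -> Path:
    extra = "".join(
        f" {k}={v}" for k, v in sorted(ms.provenance.items())
    )
    lines = [f"# qubits={ms.n_qubits} shots={ms.n_shots}{extra}"]
    for b in sorted(ms.counts):
        lines.append(f"{b} {ms.counts[b]}")
    out = Path(path)
    out.write_text("\n".join(lines) + "\n")
    return out


def read_measurements(path: str | Path) -> MeasurementSet:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValueError(f"{path}: missing '# qubits=... shots=...' header")
    header = dict(
        tok.split("=", 1) for tok in lines[0].lstrip("# ").split() if "=" in tok
    )
    n_qubits = int(header.pop("qubits"))
    declared = int(header.pop("shots"))
    counts: dict[str, int] = {}
    for line in lines[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        bits, count = line.split()
        counts[bits] = counts.get(bits, 0) + int(count)
    ms = MeasurementSet(counts, n_qubits, provenance=header)
    if ms.n_shots != declared:
        raise ValueError(
            f"{path}: header declares {declared} shots, records sum to {ms.n_shots}"
        )
    return ms
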