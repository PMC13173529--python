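"""FCIDUMP reading and writing.

The dialect accepted is the common one: a namelist header starting with
``&FCI`` carrying at least ``NORB``, ``NELEC`` and ``MS2`` (unknown keys are
ignored; comma- or whitespace-separated), terminated by ``&END`` or ``/``,
followed by data lines ``value p q r s`` with 1-based orbital indices:

* ``p q r s`` all nonzero: two-electron integral (pq|rs), chemists' notation,
  expanded to its full 8-fold symmetry class on read;
* ``r = s = 0``: one-electron integral h_pq;
* all indices zero: the core (nuclear-repulsion) energy.

Lines of the form ``value p 0 0 0`` (orbital energies, written by some
programs) are ignored.  Indices are converted to 0-based internally.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .determinants import MolecularIntegrals, SpinOrbitalBasis

__all__ = ["read_fcidump", "write_fcidump"]


class FcidumpError(ValueError):
    """Malformed FCIDUMP content; carries the offending line number."""


def _parse_header(lines: list[str]) -> tuple[dict[str, int], int]:
    if not lines or "&FCI" not in lines[0].upper():
        raise FcidumpError("line 1: missing &FCI namelist header")
    header = ""
    end = 0
    for i, line in enumerate(lines):
        header += " " + line.strip()
        end = i + 1
        if re.search(r"(&END|/)\s*$", line.strip(), re.IGNORECASE):
            break
    else:
        raise FcidumpError("header namelist never terminated with &END or /")
    fields: dict[str, int] = {}
    for m in re.finditer(r"([A-Za-z0-9_]+)\s*=\s*([-+0-9., ]+)", header):
        key = m.group(1).upper()
        first = re.split(r"[,\s]+", m.group(2).strip())[0]
        try:
            fields[key] = int(first)
        except ValueError:
            continue  # non-integer or array-valued key: ignored
    for required in ("NORB", "NELEC"):
        if required not in fields:
            raise FcidumpError(f"header is missing {required}")
    fields.setdefault("MS2", 0)
    return fields, end


def read_fcidump(path: str | Path) -> tuple[SpinOrbitalBasis, MolecularIntegrals]:
    """Parse an FCIDUMP file into a basis and integral container."""
    lines = Path(path).read_text().splitlines()
    fields, start = _parse_header(lines)
    M = fields["NORB"]
    nelec, ms2 = fields["NELEC"], fields["MS2"]
    if (nelec + ms2) % 2 != 0:
        raise FcidumpError(f"NELEC={nelec} and MS2={ms2} have odd parity")
    n_alpha = (nelec + ms2) // 2
    n_beta = (nelec - ms2) // 2

    e_core = 0.0
    h = np.zeros((M, M))
    g = np.zeros((M, M, M, M))
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        text = raw.strip()
        if not text:
            continue
        parts = text.split()
        if len(parts) != 5:
            raise FcidumpError(f"line {lineno}: expected 'value p q r s'")
        try:
            val = float(parts[0])
            p, q, r, s = (int(tok) for tok in parts[1:])
        except ValueError as exc:
            raise FcidumpError(f"line {lineno}: {exc}") from exc
        if max(p, q, r, s) > M or min(p, q, r, s) < 0:
            raise FcidumpError(
                f"line {lineno}: orbital index outside 1..NORB={M}"
            )
        if p == 0 and q == 0 and r == 0 and s == 0:
            e_core = val
        elif r == 0 and s == 0:
            if q == 0:
                continue  # orbital-energy line; not part of the Hamiltonian
            h[p - 1, q - 1] = val
            h[q - 1, p - 1] = val
        elif (p == 0) or (q == 0) or (s == 0 and r != 0):
            raise FcidumpError(f"line {lineno}: inconsistent zero indices")
        else:
            i, j, k, l = p - 1, q - 1, r - 1, s - 1
            for a, b in ((i, j), (j, i)):
                for c, d in ((k, l), (l, k)):
                    g[a, b, c, d] = val
                    g[c, d, a, b] = val
    ints = MolecularIntegrals(e_core=e_core, h=h, g=g)
    return SpinOrbitalBasis(M=M, n_alpha=n_alpha, n_beta=n_beta), ints


def _canonical_pairs(M: int):
    """Canonical (p,q,r,s) representatives of each 8-fold symmetry class."""
    for p in range(M):
        for q in range(p + 1):
            pq = p * (p + 1) // 2 + q
            for r in range(p + 1):
                for s in range(r + 1):
                    if r * (r + 1) // 2 + s <= pq:
                        yield p, q, r, s


def write_fcidump(
    basis: SpinOrbitalBasis,
    ints: MolecularIntegrals,
    path: str | Path,
    threshold: float = 1e-12,
) -> Path:
    """Write one canonical representative per symmetry class, 1-based."""
    M = basis.M
    if not np.allclose(ints.h, ints.h.T, atol=ints.symmetry_tol):
        raise ValueError("refusing to write asymmetric one-electron integrals")
    lines = [
        f"&FCI NORB={M},NELEC={basis.n_electrons},MS2={basis.n_alpha - basis.n_beta},",
        " ORBSYM=" + ",".join(["1"] * M) + ",",
        " ISYM=1,",
        "&END",
    ]
    for p, q, r, s in _canonical_pairs(M):
        val = ints.g[p, q, r, s]
        if abs(val) > threshold:
            lines.append(f"{val: .16e} {p + 1} {q + 1} {r + 1} {s + 1}")
    for p in range(M):
        for q in range(p + 1):
            if abs(ints.h[p, q]) > threshold:
                lines.append(f"{ints.h[p, q]: .16e} {p + 1} {q + 1} 0 0")
    lines.append(f"{ints.e_core: .16e} 0 0 0 0")
    out = Path(path)
    out.write_text("\n".join(lines) + "\n")
    return out
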