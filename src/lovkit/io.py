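"""Shared readers/writers: FASTA, numeric tables, newick, run manifests.

Numeric tables (spectra, kinetic traces, TCSPC histograms) are plain
comma/tab/whitespace-delimited text with optional header line and ``#``
comments; units are fixed per format (nm, s, ns, AU, Å).  Parse failures
name the offending line.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError, ParseError
from .fluorescence import DecayHistogram
from .mining import MotifHit, ConservationScore, SequenceRecord, Tree
from .photocycle import KineticTrace
from .spectra import Spectrum


def read_fasta(path) -> list[SequenceRecord]:
    """Read (possibly aligned) protein FASTA into sequence records."""
    from Bio import SeqIO

    records = [
        SequenceRecord(
            id=rec.id, seq=str(rec.seq).upper(), description=rec.description
        )
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise InputError(f"{path}: duplicate record ids")
    return records


def write_fasta(records: Sequence[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description and rec.description != rec.id:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), 60):
                fh.write(rec.seq[i : i + 60] + "\n")


def _split_line(line: str) -> list[str]:
    if "," in line:
        return [c.strip() for c in line.split(",")]
    if "\t" in line:
        return [c.strip() for c in line.split("\t")]
    return line.split()


def read_table(
    path,
    names: Sequence[str] | None = None,
    min_cols: int = 2,
    max_cols: int | None = None,
) -> pd.DataFrame:
    """Read a delimited numeric table (comma/tab/whitespace).

    A single non-numeric first row is accepted as a header; any later
    non-numeric cell raises :class:`ParseError` naming the line.
    """
    rows: list[list[float]] = []
    header: list[str] | None = None
    n_cols: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cells = _split_line(line)
            try:
                values = [float(c) for c in cells]
            except ValueError:
                if not rows and header is None:
                    header = cells
                    continue
                bad = next(
                    c for c in cells
                    if not c.replace(".", "").replace("-", "")
                    .replace("+", "").replace("e", "").replace("E", "")
                    .isdigit()
                )
                raise ParseError(
                    f"{path}: non-numeric value {bad!r} at line {lineno}"
                ) from None
            if n_cols is None:
                n_cols = len(values)
                if n_cols < min_cols:
                    raise ParseError(
                        f"{path}: expected >= {min_cols} columns, found "
                        f"{n_cols} at line {lineno}"
                    )
                if max_cols is not None and n_cols > max_cols:
                    raise ParseError(
                        f"{path}: expected <= {max_cols} columns, found "
                        f"{n_cols} at line {lineno}"
                    )
            elif len(values) != n_cols:
                raise ParseError(
                    f"{path}: inconsistent column count at line {lineno}"
                )
            rows.append(values)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    if names is not None:
        if len(names) != n_cols:
            raise ParseError(
                f"{path}: schema expects {len(names)} columns, file has "
                f"{n_cols}"
            )
        columns = list(names)
    elif header is not None and len(header) == n_cols:
        columns = header
    else:
        columns = [f"col{i}" for i in range(n_cols)]
    return pd.DataFrame(rows, columns=columns)


def read_spectrum(path, meta: dict | None = None) -> Spectrum:
    """Two-column spectrum file: wavelength (nm), signal."""
    df = read_table(path, min_cols=2, max_cols=2)
    return Spectrum(
        wavelengths=df.iloc[:, 0].to_numpy(),
        values=df.iloc[:, 1].to_numpy(),
        meta=meta or {},
    )


def read_kinetic_trace(
    path, monitor_nm: float = 446.0, path_cm: float = 1.0
) -> KineticTrace:
    """Two-column kinetics file: time (s), absorbance (AU)."""
    df = read_table(path, min_cols=2, max_cols=2)
    return KineticTrace(
        times=df.iloc[:, 0].to_numpy(),
        absorbance=df.iloc[:, 1].to_numpy(),
        monitor_nm=monitor_nm,
        path_cm=path_cm,
    )


def read_decay_histogram(
    path,
    irf_path=None,
    lambda_ex: float = 461.0,
    lambda_em: float = 500.0,
) -> DecayHistogram:
    """TCSPC histogram: time (ns), counts[, irf_counts].

    A two-column file needs ``irf_path`` (same binning) for the IRF.
    """
    df = read_table(path, min_cols=2, max_cols=3)
    times = df.iloc[:, 0].to_numpy()
    counts = df.iloc[:, 1].to_numpy()
    if df.shape[1] == 3:
        irf = df.iloc[:, 2].to_numpy()
    else:
        if irf_path is None:
            raise InputError(
                f"{path}: two-column decay file requires irf_path"
            )
        irf_df = read_table(irf_path, min_cols=2, max_cols=2)
        irf = irf_df.iloc[:, 1].to_numpy()
        if irf.size != times.size:
            raise InputError("IRF and decay histograms differ in binning")
    return DecayHistogram(
        times=times,
        counts=counts,
        irf_counts=irf,
        lambda_ex=lambda_ex,
        lambda_em=lambda_em,
    )


def read_positions_table(path) -> dict[int, set[str]]:
    """Conserved-position table: column <tab> allowed residues (e.g. 'DE')."""
    out: dict[int, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cells = _split_line(line)
            if len(cells) != 2:
                raise ParseError(
                    f"{path}: expected 2 columns at line {lineno}"
                )
            try:
                col = int(cells[0])
            except ValueError:
                if lineno == 1 or not out:
                    continue  # header
                raise ParseError(
                    f"{path}: non-integer column at line {lineno}"
                ) from None
            out[col] = set(cells[1])
    if not out:
        raise ParseError(f"{path}: no positions")
    return out


def read_reference_scale(path) -> dict[str, float]:
    """Residue max-ASA scale: three-letter code <tab> area (Å²)."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cells = _split_line(line)
            if len(cells) != 2:
                raise ParseError(
                    f"{path}: expected 2 columns at line {lineno}"
                )
            try:
                out[cells[0].upper()] = float(cells[1])
            except ValueError:
                if not out:
                    continue
                raise ParseError(
                    f"{path}: non-numeric area at line {lineno}"
                ) from None
    if not out:
        raise ParseError(f"{path}: no scale entries")
    return out


def write_newick(tree: Tree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def motif_hits_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "record_id": h.record_id,
                "start": h.start,
                "matched": h.matched,
                "variant_class": h.variant_class,
            }
            for h in hits
        ],
        columns=["record_id", "start", "matched", "variant_class"],
    )


def conservation_frame(scores: Sequence[ConservationScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "record_id": s.record_id,
                "n_checked": s.n_checked,
                "n_matched": s.n_matched,
                "fraction": s.fraction,
            }
            for s in scores
        ],
        columns=["record_id", "n_checked", "n_matched", "fraction"],
    )


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path,
    command: str,
    inputs: Sequence[str],
    parameters: dict,
    outputs: Sequence[str],
) -> None:
    """Provenance manifest: inputs, parameters, outputs with SHA-256 hashes."""
    from . import __version__

    manifest = {
        "tool": "lovkit",
        "version": __version__,
        "command": command,
        "parameters": parameters,
        "inputs": [
            {"path": str(p), "sha256": sha256_file(p)} for p in inputs
        ],
        "outputs": [
            {"path": str(p), "sha256": sha256_file(p)} for p in outputs
        ],
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
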