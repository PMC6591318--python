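"""Readers and writers for the plain-text formats the pipeline speaks.

FASTA for proteins (Biopython-backed), MGF for spectra (pyteomics-backed)
and a simple two-column TSV peak-list format with a ``#key<TAB>value``
metadata header.  Every writer's output round-trips through the matching
reader without loss of the fields the pipeline uses.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from pyteomics import mgf as _mgf

from .digestion import ProteinRecord
from .laddersearch import PeakList

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_peaklists",
    "write_mgf",
    "read_tsv_peaklist",
    "write_tsv_peaklist",
]

logger = logging.getLogger(__name__)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into protein records.

    Wrapped sequence lines are concatenated; a trailing ``*`` stop codon
    is stripped with a warning; duplicate record ids are rejected.
    """
    path = Path(path)
    _validate_fasta_layout(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            logger.warning("stripping trailing stop codon '*' from %s", rec.id)
            seq = seq[:-1]
        if "*" in seq:
            raise ValueError(
                f"internal stop codon in FASTA record {rec.id!r}"
            )
        records.append(
            ProteinRecord(id=rec.id, sequence=seq, description=rec.description)
        )
    return records


def _validate_fasta_layout(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}:{lineno}: expected a '>' header before sequence data"
                )
            return  # first meaningful line is a header; SeqIO handles the rest


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def _sorted_peaks(
    mzs: Sequence[float], intensities: Sequence[float], source: str
) -> tuple[tuple[float, float], ...]:
    pairs = list(zip(mzs, intensities))
    if any(m <= 0 for m, _ in pairs):
        raise ValueError(f"negative or zero m/z in {source}")
    if pairs != sorted(pairs, key=lambda p: p[0]):
        logger.warning("unsorted peaks in %s; sorting", source)
        pairs.sort(key=lambda p: p[0])
    return tuple((float(m), float(i)) for m, i in pairs)


def read_peaklists(path: str | Path) -> list[PeakList]:
    """Read peak lists from an MGF file or a TSV peak list.

    The format is chosen by extension (``.mgf`` vs anything else).
    An empty file yields an empty list with a warning.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        logger.warning("empty peak-list file %s", path)
        return []
    if path.suffix.lower() == ".mgf":
        return _read_mgf(path)
    return [read_tsv_peaklist(path)]


def _read_mgf(path: Path) -> list[PeakList]:
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pyteomics warns on absent indices
        with _mgf.MGF(str(path)) as reader:
            for i, spectrum in enumerate(reader):
                params = spectrum.get("params", {})
                pepmass = params.get("pepmass")
                precursor_mz = float(pepmass[0]) if pepmass else None
                charge_list = params.get("charge")
                charge = int(charge_list[0]) if charge_list else None
                ms_level = 2 if precursor_mz is not None else 1
                out.append(
                    PeakList(
                        peaks=_sorted_peaks(
                            spectrum["m/z array"],
                            spectrum["intensity array"],
                            f"{path}#{i}",
                        ),
                        ms_level=ms_level,
                        precursor_mz=precursor_mz,
                        precursor_charge=charge,
                        source_id=str(params.get("title", f"{path.name}#{i}")),
                    )
                )
    return out


def write_mgf(peaklists: Iterable[PeakList], path: str | Path) -> None:
    spectra = []
    for pl in peaklists:
        params: dict = {"title": pl.source_id}
        if pl.precursor_mz is not None:
            params["pepmass"] = pl.precursor_mz
        if pl.precursor_charge is not None:
            params["charge"] = pl.precursor_charge
        spectra.append(
            {
                "params": params,
                "m/z array": [p[0] for p in pl.peaks],
                "intensity array": [p[1] for p in pl.peaks],
            }
        )
    _mgf.write(spectra, str(path), file_mode="w")


def read_tsv_peaklist(path: str | Path) -> PeakList:
    """Read a two-column (m/z, intensity) TSV with ``#key<TAB>value`` metadata."""
    path = Path(path)
    meta: dict[str, str] = {}
    mzs: list[float] = []
    intensities: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                meta[key.strip()] = value.strip()
                continue
            cols = line.split("\t")
            if cols[0].lower() in ("mz", "m/z"):
                continue  # column header
            mzs.append(float(cols[0]))
            intensities.append(float(cols[1]) if len(cols) > 1 else 0.0)
    return PeakList(
        peaks=_sorted_peaks(mzs, intensities, str(path)),
        ms_level=int(meta.get("ms_level", "1")),
        precursor_mz=(
            float(meta["precursor_mz"]) if "precursor_mz" in meta else None
        ),
        precursor_charge=(
            int(meta["precursor_charge"]) if "precursor_charge" in meta else None
        ),
        source_id=meta.get("source_id", path.stem),
    )


def write_tsv_peaklist(peaklist: PeakList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#ms_level\t{peaklist.ms_level}\n")
        if peaklist.precursor_mz is not None:
            fh.write(f"#precursor_mz\t{peaklist.precursor_mz!r}\n")
        if peaklist.precursor_charge is not None:
            fh.write(f"#precursor_charge\t{peaklist.precursor_charge}\n")
        if peaklist.source_id:
            fh.write(f"#source_id\t{peaklist.source_id}\n")
        fh.write("mz\tintensity\n")
        for mz_value, intensity in peaklist.peaks:
            fh.write(f"{mz_value!r}\t{intensity!r}\n")
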