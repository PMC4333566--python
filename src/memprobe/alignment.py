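"""Per-column conservation and hydrophobic-class conservation from an MSA.

The central quantity is, for each reference-sequence residue, the percentage
of aligned sequences whose residue at that column (i) matches the most common
residue (identity conservation) and (ii) belongs to a configurable residue
class — by default the hydrophobic set {M, A, V, I, L, C, Y, F, W} used to
locate buried helix faces in membrane transporters.

Columns where the reference carries a gap are skipped, so positions map
1-based onto the ungapped reference sequence (residue labels like W300 refer
to this numbering).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

__all__ = [
    "GAP",
    "STANDARD_AA",
    "HYDROPHOBIC_CLASS",
    "Alignment",
    "ConservationConfig",
    "ConservationProfile",
    "AlignmentFormatError",
    "read_alignment",
    "conservation_profile",
    "conservation_heatmap_matrix",
    "write_profile_tsv",
    "write_profile_json",
    "read_profile_tsv",
    "write_alignment_fasta",
]

GAP = "-"
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Hydrophobic residue class used for buried-face conservation heat maps.
HYDROPHOBIC_CLASS = frozenset("MAVILCYFW")

_FORMAT_BY_EXT = {
    ".fasta": "fasta",
    ".fa": "fasta",
    ".afa": "fasta",
    ".aln": "clustal",
    ".clustal": "clustal",
}


class AlignmentFormatError(ValueError):
    """Raised for ragged alignments or unparseable alignment files."""


@dataclass
class Alignment:
    """A gapped sequence matrix with a designated reference row.

    The reference row defines residue numbering: its k-th non-gap column is
    residue k (1-based).
    """

    ids: list[str]
    rows: list[str]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentFormatError("alignment has no rows")
        if len(self.ids) != len(self.rows):
            raise AlignmentFormatError("ids and rows differ in length")
        length = len(self.rows[0])
        if length < 1:
            raise AlignmentFormatError("alignment rows are empty")
        for sid, row in zip(self.ids, self.rows):
            if len(row) != length:
                raise AlignmentFormatError(
                    f"ragged alignment: row {sid!r} has length {len(row)}, "
                    f"expected {length}"
                )
        if self.reference_id not in self.ids:
            raise KeyError(f"reference id {self.reference_id!r} not in alignment")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def reference_row(self) -> str:
        return self.rows[self.ids.index(self.reference_id)]

    def matrix(self) -> np.ndarray:
        """Character matrix of shape (n_rows, length), upper-case."""
        return np.array([list(r.upper()) for r in self.rows], dtype="<U1")


@dataclass
class ConservationConfig:
    """Options for the conservation computation.

    gap_policy selects the percentage denominator: ``all_rows`` counts gaps
    against conservation (every row contributes to the denominator),
    ``nongap_rows`` restricts the denominator to rows with a residue at the
    column.
    """

    residue_class: frozenset[str] = HYDROPHOBIC_CLASS
    gap_policy: str = "all_rows"

    def __post_init__(self) -> None:
        self.residue_class = frozenset(c.upper() for c in self.residue_class)
        if not self.residue_class:
            raise ValueError("residue_class must be non-empty")
        if not self.residue_class <= STANDARD_AA:
            bad = sorted(self.residue_class - STANDARD_AA)
            raise ValueError(f"residue_class contains non-standard letters: {bad}")
        if self.gap_policy not in ("all_rows", "nongap_rows"):
            raise ValueError(f"unknown gap_policy {self.gap_policy!r}")


@dataclass
class ConservationProfile:
    """Per-reference-residue conservation percentages."""

    positions: np.ndarray  # 1-based reference residue numbers
    reference_residues: np.ndarray
    modal_residues: np.ndarray
    identity_pct: np.ndarray
    class_pct: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "reference_residue": self.reference_residues,
                "modal_residue": self.modal_residues,
                "identity_pct": self.identity_pct,
                "class_pct": self.class_pct,
            }
        )


def read_alignment(path: str | Path, reference_id: str, format: str | None = None) -> Alignment:
    """Read an aligned FASTA or Clustal file.

    The format is inferred from the extension when not given explicitly.
    """
    path = Path(path)
    if format is None:
        try:
            format = _FORMAT_BY_EXT[path.suffix.lower()]
        except KeyError:
            raise AlignmentFormatError(
                f"cannot infer alignment format from extension {path.suffix!r}"
            ) from None
    if format not in ("fasta", "clustal"):
        raise AlignmentFormatError(f"unsupported alignment format {format!r}")
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise AlignmentFormatError(f"failed to parse {path}: {exc}") from exc
    ids = [rec.id for rec in msa]
    rows = [str(rec.seq).upper() for rec in msa]
    aln = Alignment(ids=ids, rows=rows, reference_id=reference_id)
    letters = set("".join(rows)) - STANDARD_AA - {GAP, "."}
    if letters:
        warnings.warn(
            f"{path.name}: nonstandard letters {sorted(letters)} treated as "
            "non-class, non-identity residues",
            stacklevel=2,
        )
    return aln


def write_alignment_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")


def conservation_profile(
    aln: Alignment, cfg: ConservationConfig | None = None
) -> ConservationProfile:
    """Compute identity and residue-class conservation per reference residue.

    Gaps are never counted as residues; whether they count in the denominator
    is governed by ``cfg.gap_policy``. Ties for the modal residue break
    alphabetically so reports are deterministic.
    """
    cfg = cfg or ConservationConfig()
    mat = aln.matrix()
    ref = np.array(list(aln.reference_row.upper()), dtype="<U1")
    ref_nongap = (ref != GAP) & (ref != ".")
    if not ref_nongap.any():
        raise ValueError("reference row is all gaps; profile would be empty")

    class_arr = np.array(sorted(cfg.residue_class), dtype="<U1")
    positions, ref_res, modal, ident, cls = [], [], [], [], []
    pos = 0
    for col_idx in np.nonzero(ref_nongap)[0]:
        pos += 1
        col = mat[:, col_idx]
        residue_mask = np.isin(col, list(STANDARD_AA))
        nongap_mask = (col != GAP) & (col != ".")
        denom = aln.n_rows if cfg.gap_policy == "all_rows" else int(nongap_mask.sum())
        letters, counts = np.unique(col[residue_mask], return_counts=True)
        if letters.size:
            best = letters[np.lexsort((letters, -counts))][0]  # ties: alphabetical
            n_modal = int(counts[letters == best][0])
        else:
            best, n_modal = GAP, 0
        n_class = int(np.isin(col, class_arr).sum())
        positions.append(pos)
        ref_res.append(ref[col_idx])
        modal.append(best)
        ident.append(100.0 * n_modal / denom if denom else 0.0)
        cls.append(100.0 * n_class / denom if denom else 0.0)

    return ConservationProfile(
        positions=np.array(positions, dtype=int),
        reference_residues=np.array(ref_res, dtype="<U1"),
        modal_residues=np.array(modal, dtype="<U1"),
        identity_pct=np.array(ident, dtype=float),
        class_pct=np.array(cls, dtype=float),
    )


def conservation_heatmap_matrix(
    profile: ConservationProfile, window: int | None = None
) -> np.ndarray:
    """Arrange class-conservation values for plotting.

    Without ``window``: an (n, 2) array of (position, class_pct) pairs.
    With ``window``: class_pct wrapped into rows of ``window`` columns
    (NaN-padded), the layout used for strip-style heat maps.
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    if window is None:
        return np.column_stack([profile.positions.astype(float), profile.class_pct])
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(profile)
    n_rows = -(-n // window)
    out = np.full(n_rows * window, np.nan)
    out[:n] = profile.class_pct
    return out.reshape(n_rows, window)


def write_profile_tsv(profile: ConservationProfile, path: str | Path) -> None:
    # default float formatting (repr) so percentages round-trip exactly
    profile.to_frame().to_csv(path, sep="\t", index=False)


def read_profile_tsv(path: str | Path) -> ConservationProfile:
    df = pd.read_csv(path, sep="\t")
    return ConservationProfile(
        positions=df["position"].to_numpy(int),
        reference_residues=df["reference_residue"].to_numpy("<U1"),
        modal_residues=df["modal_residue"].to_numpy("<U1"),
        identity_pct=df["identity_pct"].to_numpy(float),
        class_pct=df["class_pct"].to_numpy(float),
    )


def write_profile_json(profile: ConservationProfile, path: str | Path) -> None:
    payload = {
        "position": profile.positions.tolist(),
        "reference_residue": profile.reference_residues.tolist(),
        "modal_residue": profile.modal_residues.tolist(),
        "identity_pct": profile.identity_pct.tolist(),
        "class_pct": profile.class_pct.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
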