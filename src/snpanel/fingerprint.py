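"""Cultivar fingerprint database over a fixed core marker panel.

Each sample gets a genotype string over the ordered panel; samples with
identical strings fall into duplicate groups (candidate synonyms or
re-released cultivars). The database also exports the fingerprint
matrix and a compact plain-text barcode payload per sample (one symbol
per marker: R=hom-ref, H=het, A=hom-alt, N=missing) carrying a panel
hash so payloads are never decoded against the wrong panel.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from . import io as _io
from .model import Call, GenotypeMatrix
from .panel import GenotypeString, _group_samples, genotype_string, panel_hash

_CALL_TO_CODE = {Call.HOM_REF: "R", Call.HET: "H", Call.HOM_ALT: "A", Call.MISSING: "N"}
_CODE_TO_CALL = {v: k for k, v in _CALL_TO_CODE.items()}

PAYLOAD_PREFIX = "FP1"


class PanelMismatchError(ValueError):
    pass


@dataclass
class FingerprintDB:
    """Fingerprints of all samples over one fixed panel.

    `groups` partitions the samples into identical-genotype groups
    (singletons are fully distinguished samples); the number of groups
    equals the panel's distinct-genotype count.
    """

    matrix: GenotypeMatrix  # panel-subset call matrix, panel order
    entries: dict[str, GenotypeString]
    groups: list[list[str]]
    missing_mode: str
    hash: str

    @property
    def panel(self) -> list[str]:
        return self.matrix.marker_ids

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_distinguished(self) -> int:
        return sum(1 for g in self.groups if len(g) == 1)


def build_db(
    matrix: GenotypeMatrix,
    panel: Sequence[str],
    missing_mode: str = "distinct",
) -> FingerprintDB:
    """Fingerprint every sample over `panel` and group identical
    genotypes (grouping honors the chosen missing-data mode)."""
    panel = list(panel)
    if not panel:
        raise ValueError("panel must contain at least one marker")
    sub = matrix.select_markers(panel)
    entries = {s: genotype_string(sub, s, panel) for s in sub.samples}
    idx_groups = _group_samples(sub.calls, missing_mode)
    groups = [sorted(sub.samples[i] for i in g) for g in idx_groups]
    groups.sort(key=lambda g: (-len(g), g[0]))
    return FingerprintDB(
        matrix=sub,
        entries=entries,
        groups=groups,
        missing_mode=missing_mode,
        hash=panel_hash(matrix, panel),
    )


def duplicate_report(db: FingerprintDB) -> pd.DataFrame:
    """Non-singleton genotype groups, largest first (ties broken by the
    first member name), with the shared genotype string."""
    rows = []
    for g in db.groups:
        if len(g) < 2:
            continue
        rows.append(
            {
                "size": len(g),
                "genotype": db.entries[g[0]].joined,
                "members": ",".join(g),
            }
        )
    df = pd.DataFrame(rows, columns=["size", "genotype", "members"])
    if not df.empty:
        df = df.sort_values(
            ["size", "members"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
    return df


def export_matrix(db: FingerprintDB, path: str | os.PathLike) -> None:
    """Fingerprint matrix TSV: markers as rows, samples as columns,
    cells 0/0, 0/1, 1/1 or ./.; round-trips through the genotype-table
    reader."""
    _io.write_genotype_table(db.matrix, path, orient="markers-rows")


def export_json(db: FingerprintDB, path: str | os.PathLike) -> None:
    payload = {
        "panel_hash": db.hash,
        "missing_mode": db.missing_mode,
        "panel": [
            {"id": m.id, "chrom": m.chrom, "pos": m.pos, "ref": m.ref, "alt": m.alt}
            for m in db.matrix.markers
        ],
        "fingerprints": {s: db.entries[s].joined for s in db.matrix.samples},
        "groups": db.groups,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def encode_barcode(db: FingerprintDB, sample: str) -> str:
    """Plain-text barcode payload for one sample:
    "FP1|<panel-hash>|<sample>|<call codes>"."""
    if sample not in db.entries:
        raise KeyError(f"sample {sample!r} not in database")
    row = db.matrix.row(sample)
    codes = "".join(_CALL_TO_CODE[Call(int(c))] for c in row)
    return f"{PAYLOAD_PREFIX}|{db.hash}|{sample}|{codes}"


def decode_barcode(payload: str, db: FingerprintDB) -> tuple[str, list[Call]]:
    """Decode a payload back to (sample_id, calls); fails loudly on a
    panel-hash mismatch or a malformed payload."""
    parts = payload.split("|")
    if len(parts) != 4 or parts[0] != PAYLOAD_PREFIX:
        raise ValueError(f"malformed barcode payload: {payload!r}")
    _, phash, sample, codes = parts
    if phash != db.hash:
        raise PanelMismatchError(
            f"payload panel hash {phash} != database panel hash {db.hash}"
        )
    if len(codes) != len(db.panel):
        raise ValueError(
            f"payload encodes {len(codes)} markers, panel has {len(db.panel)}"
        )
    try:
        calls = [_CODE_TO_CALL[c] for c in codes]
    except KeyError as exc:
        raise ValueError(f"invalid call code {exc} in payload") from None
    return sample, calls
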