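"""Readers and writers for every on-disk format.

Formats
-------
* PDB v3.3 fixed-column ATOM/HETATM records (atoms only; no models/ANISOU).
* Cavity records as JSON-Lines, one cavity per line.
* Token corpus: one cavity per line, ``cavity_id<TAB>tok tok tok``.
* Embeddings in word2vec text format: header ``V d`` then one token+vector
  per line.

All floats are written with 6 significant digits; every reader rejects
malformed input with the offending line number rather than repairing it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ParseError, SchemaError
from .structures import Atom, CavityRecord, CavitySequence, vdw_radius_for

_FLOAT_FMT = "%.6g"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % float(x)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str) -> str:
    """Element from the atom-name columns when the element field is blank.

    PDB names right-justify the element in columns 13-14; names like
    " CA " are carbon, "1HB " is hydrogen. Strategy: drop digits, take the
    first remaining letter (two letters only for common two-letter elements).
    """
    stripped = atom_name.strip()
    letters = "".join(ch for ch in stripped if ch.isalpha())
    if not letters:
        return ""
    two = letters[:2].upper()
    if two in ("CL", "BR", "FE", "ZN", "MG", "NA", "MN", "CU", "SE"):
        return two.capitalize()
    return letters[0].upper()


def read_pdb(path) -> list[Atom]:
    """Parse ATOM/HETATM records from a PDB v3.3 file.

    HETATM atoms are flagged ``is_hetero``; water is detectable through
    :attr:`Atom.is_water`. Unknown elements get the default vdW radius.
    """
    path = Path(path)
    atoms: list[Atom] = []
    seen_serials: set[int] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            rec = line[:6]
            if rec not in ("ATOM  ", "HETATM") and rec.strip() not in ("ATOM", "HETATM"):
                continue
            try:
                serial = int(line[6:11])
                name = line[12:16]
                res_name = line[17:20].strip()
                chain = line[21].strip() or " "
                res_seq = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise ParseError(f"malformed fixed-width field ({exc})",
                                 path=path, line=lineno) from exc
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = _infer_element(name)
            if serial in seen_serials:
                raise ParseError(f"duplicate atom serial {serial}", path=path, line=lineno)
            seen_serials.add(serial)
            atoms.append(Atom(
                serial=serial,
                name=name.strip(),
                element=element,
                res_name=res_name,
                res_seq=res_seq,
                chain=chain,
                position=np.array([x, y, z]),
                vdw_radius=vdw_radius_for(element),
                is_hetero=(rec.strip() == "HETATM"),
            ))
    if not atoms:
        raise ParseError("no ATOM/HETATM records found", path=path)
    return atoms


def write_pdb(atoms: Iterable[Atom], path) -> None:
    """Write atoms as fixed-column PDB v3.3 ATOM/HETATM records."""
    path = Path(path)
    with open(path, "w") as fh:
        for atom in atoms:
            rec = "HETATM" if atom.is_hetero else "ATOM  "
            name = atom.name
            # short names start in column 14 by convention
            name_field = name.ljust(4) if len(name) >= 4 else (" " + name).ljust(4)
            x, y, z = atom.position
            fh.write(
                f"{rec}{atom.serial:5d} {name_field}"
                f" {atom.res_name:<3s} {atom.chain:1s}{atom.res_seq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {atom.element:>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Cavity records (JSONL)
# ---------------------------------------------------------------------------

_REQUIRED_CAVITY_KEYS = ("cavity_id", "snapshot", "spheres")


def read_cavity_records(path) -> list[CavityRecord]:
    """Read JSON-Lines cavity records, preserving record and sphere order."""
    path = Path(path)
    records: list[CavityRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"invalid JSON ({exc.msg})", path=path, line=lineno) from exc
            for key in _REQUIRED_CAVITY_KEYS:
                if key not in obj:
                    raise SchemaError(f"missing required key '{key}'", path=path, line=lineno)
            spheres = obj["spheres"]
            if not spheres:
                raise SchemaError("cavity has zero spheres", path=path, line=lineno)
            try:
                centers = np.array([s["center"] for s in spheres], dtype=float)
                radii = np.array([s["radius"] for s in spheres], dtype=float)
            except (KeyError, TypeError, ValueError) as exc:
                raise SchemaError(f"malformed sphere entry ({exc})",
                                  path=path, line=lineno) from exc
            lining = obj.get("lining_atom_serials")
            if lining is not None:
                lining = [tuple(int(s) for s in quad) for quad in lining]
            try:
                rec = CavityRecord(
                    cavity_id=str(obj["cavity_id"]),
                    snapshot=int(obj["snapshot"]),
                    centers=centers,
                    radii=radii,
                    node_ids=obj.get("node_ids"),
                    lining_atom_serials=lining,
                )
            except ValueError as exc:
                raise SchemaError(str(exc), path=path, line=lineno) from exc
            records.append(rec)
    return records


def write_cavity_records(records: Iterable[CavityRecord], path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            obj: dict = {
                "cavity_id": rec.cavity_id,
                "snapshot": int(rec.snapshot),
                "spheres": [
                    {
                        "center": [float(_fmt(c)) for c in center],
                        "radius": float(_fmt(r)),
                    }
                    for center, r in zip(rec.centers, rec.radii)
                ],
            }
            if rec.node_ids is not None:
                obj["node_ids"] = list(rec.node_ids)
            if rec.lining_atom_serials is not None:
                obj["lining_atom_serials"] = [list(q) for q in rec.lining_atom_serials]
            fh.write(json.dumps(obj) + "\n")


# ---------------------------------------------------------------------------
# Corpus
# ---------------------------------------------------------------------------

def write_corpus(sequences, path) -> None:
    """Write cavity sentences, one per line: ``cavity_id<TAB>tok tok ...``.

    Accepts CavitySequence objects or ``(cavity_id, tokens)`` pairs.
    """
    path = Path(path)
    seen: set[str] = set()
    with open(path, "w") as fh:
        for item in sequences:
            if isinstance(item, CavitySequence):
                cid, tokens = item.cavity_id, item.tokens
            else:
                cid, tokens = item
            if cid in seen:
                raise ValueError(f"duplicate cavity_id '{cid}' in corpus")
            seen.add(cid)
            if not tokens:
                raise ValueError(f"cavity '{cid}' has no tokens")
            for tok in tokens:
                if not tok or any(ch.isspace() for ch in tok):
                    raise ValueError(f"cavity '{cid}': token {tok!r} is empty or has whitespace")
            fh.write(f"{cid}\t{' '.join(tokens)}\n")


def read_corpus(path) -> list[tuple[str, list[str]]]:
    """Exact inverse of :func:`write_corpus`; preserves order."""
    path = Path(path)
    out: list[tuple[str, list[str]]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if "\t" not in line:
                raise ParseError("corpus line has no TAB separator", path=path, line=lineno)
            cid, _, rest = line.partition("\t")
            tokens = rest.split(" ") if rest else []
            if not tokens or any(t == "" for t in tokens):
                raise ParseError(f"cavity '{cid}': empty token", path=path, line=lineno)
            if cid in seen:
                raise ParseError(f"duplicate cavity_id '{cid}'", path=path, line=lineno)
            seen.add(cid)
            out.append((cid, tokens))
    return out


# ---------------------------------------------------------------------------
# Embeddings (word2vec text format)
# ---------------------------------------------------------------------------

def write_embeddings(vectors, path) -> None:
    """Write token vectors in word2vec text format.

    ``vectors`` is a mapping token -> 1-D array, or an EmbeddingModel
    (its input vectors are written).
    """
    if hasattr(vectors, "vocabulary") and hasattr(vectors, "input_vectors"):
        model = vectors
        vectors = {tok: model.input_vectors[i]
                   for i, tok in enumerate(model.vocabulary.tokens)}
    path = Path(path)
    items = list(vectors.items()) if isinstance(vectors, Mapping) else list(vectors)
    if not items:
        raise ValueError("no vectors to write")
    dim = len(np.asarray(items[0][1]))
    with open(path, "w") as fh:
        fh.write(f"{len(items)} {dim}\n")
        for tok, vec in items:
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (dim,):
                raise ValueError(f"token '{tok}': dimension {vec.shape} != ({dim},)")
            fh.write(tok + " " + " ".join(_fmt(v) for v in vec) + "\n")


def read_embeddings(path) -> dict[str, np.ndarray]:
    """Read word2vec-text vectors; insertion order follows the file."""
    path = Path(path)
    out: dict[str, np.ndarray] = {}
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ParseError("expected header 'V d'", path=path, line=1)
        try:
            n_tokens, dim = int(header[0]), int(header[1])
        except ValueError as exc:
            raise ParseError("non-integer header fields", path=path, line=1) from exc
        for lineno, raw in enumerate(fh, start=2):
            parts = raw.split()
            if not parts:
                continue
            tok, values = parts[0], parts[1:]
            if len(values) != dim:
                raise ParseError(f"token '{tok}': expected {dim} floats, got {len(values)}",
                                 path=path, line=lineno)
            if tok in out:
                raise ParseError(f"duplicate token '{tok}'", path=path, line=lineno)
            out[tok] = np.array([float(v) for v in values])
    if len(out) != n_tokens:
        raise ParseError(f"header declares {n_tokens} vectors, file has {len(out)}",
                         path=path)
    return out


# ---------------------------------------------------------------------------
# Small tabular helpers (TSV assignments / labels)
# ---------------------------------------------------------------------------

def write_labels_tsv(labels: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for cid, lab in labels.items():
            fh.write(f"{cid}\t{lab}\n")


def read_labels_tsv(path) -> dict[str, int]:
    path = Path(path)
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if "\t" not in line:
                raise ParseError("labels line has no TAB", path=path, line=lineno)
            cid, _, lab = line.partition("\t")
            out[cid] = int(lab)
    return out
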