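"""PBN JSON serialization and MatrixMarket export.

The JSON layout (round-trips exactly)::

    {
      "n": 2, "m": 1, "K": 2, "p": 0.0,
      "representation": "per_gene",
      "genes": [[{"parents": [1], "table": [0, 1], "c": 1.0}, ...], ...]
    }

or, for the explicit form::

    {
      ...,
      "representation": "constituents",
      "constituents": [{"q": 0.5,
                        "functions": [{"parents": [1], "table": [0, 1]}, ...]},
                       ...]
    }

Files are validated structurally on load; violations are reported with the
JSON path of the offending element.  Transition matrices are written in
MatrixMarket coordinate format (1-based indices), one file per control value.
"""

from __future__ import annotations

import json
from pathlib import Path

import scipy.io
import scipy.sparse as sp

from .model import (
    BooleanFunction,
    Constituent,
    ControlledTransitionModel,
    ProbabilisticBooleanNetwork,
)


class SchemaError(ValueError):
    """A PBN JSON document violates the expected layout."""

    def __init__(self, path: str, message: str) -> None:
        super().__init__(f"at {path}: {message}")
        self.json_path = path


def _expect(cond: bool, path: str, msg: str) -> None:
    if not cond:
        raise SchemaError(path, msg)


def _check_function(obj, path: str, need_c: bool) -> dict:
    _expect(isinstance(obj, dict), path, "expected an object")
    for key in ("parents", "table"):
        _expect(key in obj, path, f"missing '{key}'")
    _expect(
        isinstance(obj["parents"], list)
        and all(isinstance(p, int) and p >= 1 for p in obj["parents"]),
        f"{path}.parents", "expected a list of 1-based integers",
    )
    _expect(
        isinstance(obj["table"], list) and all(b in (0, 1) for b in obj["table"]),
        f"{path}.table", "expected a list of 0/1 entries",
    )
    _expect(
        len(obj["table"]) == 1 << len(obj["parents"]),
        f"{path}.table",
        f"length {len(obj['table'])} != 2^{len(obj['parents'])} for the listed parents",
    )
    if need_c:
        _expect("c" in obj and isinstance(obj["c"], (int, float)),
                f"{path}.c", "missing numeric selection probability")
    return obj


def validate_pbn_document(doc) -> None:
    """Structural validation of a loaded PBN JSON document."""
    _expect(isinstance(doc, dict), "$", "expected a JSON object")
    for key in ("n", "m", "representation"):
        _expect(key in doc, "$", f"missing '{key}'")
    _expect(isinstance(doc["n"], int) and doc["n"] >= 1, "$.n", "need integer n >= 1")
    _expect(isinstance(doc["m"], int) and doc["m"] >= 0, "$.m", "need integer m >= 0")
    rep = doc["representation"]
    _expect(rep in ("per_gene", "constituents"), "$.representation",
            "must be 'per_gene' or 'constituents'")
    if rep == "per_gene":
        _expect("genes" in doc and isinstance(doc["genes"], list),
                "$.genes", "missing gene function lists")
        _expect(len(doc["genes"]) == doc["n"], "$.genes",
                f"{len(doc['genes'])} gene entries for n={doc['n']}")
        for i, fs in enumerate(doc["genes"]):
            _expect(isinstance(fs, list) and fs, f"$.genes[{i}]",
                    "expected a non-empty function list")
            for j, f in enumerate(fs):
                _check_function(f, f"$.genes[{i}][{j}]", need_c=True)
    else:
        _expect("constituents" in doc and isinstance(doc["constituents"], list)
                and doc["constituents"], "$.constituents",
                "missing constituent list")
        for j, c in enumerate(doc["constituents"]):
            path = f"$.constituents[{j}]"
            _expect(isinstance(c, dict) and "q" in c and "functions" in c,
                    path, "expected {q, functions}")
            _expect(isinstance(c["functions"], list)
                    and len(c["functions"]) == doc["n"], f"{path}.functions",
                    f"expected one function per gene (n={doc['n']})")
            for i, f in enumerate(c["functions"]):
                _check_function(f, f"{path}.functions[{i}]", need_c=False)


def pbn_to_document(pbn: ProbabilisticBooleanNetwork) -> dict:
    doc: dict = {
        "n": pbn.n, "m": pbn.m, "K": pbn.K, "p": pbn.p,
        "representation": pbn.representation,
    }
    if pbn.genes is not None:
        doc["genes"] = [
            [{"parents": list(f.parents), "table": list(f.table), "c": f.c}
             for f in fs]
            for fs in pbn.genes
        ]
    else:
        assert pbn.constituents is not None
        doc["constituents"] = [
            {"q": c.q,
             "functions": [{"parents": list(f.parents), "table": list(f.table)}
                           for f in c.functions]}
            for c in pbn.constituents
        ]
    return doc


def document_to_pbn(doc: dict) -> ProbabilisticBooleanNetwork:
    validate_pbn_document(doc)
    kw = dict(n=doc["n"], m=doc["m"], p=doc.get("p", 0.0) or 0.0, K=doc.get("K"))
    if doc["representation"] == "per_gene":
        genes = [
            [BooleanFunction(tuple(f["parents"]), tuple(f["table"]), float(f["c"]))
             for f in fs]
            for fs in doc["genes"]
        ]
        return ProbabilisticBooleanNetwork(genes=genes, **kw)
    consts = [
        Constituent(
            q=float(c["q"]),
            functions=tuple(
                BooleanFunction(tuple(f["parents"]), tuple(f["table"]))
                for f in c["functions"]
            ),
        )
        for c in doc["constituents"]
    ]
    return ProbabilisticBooleanNetwork(constituents=consts, **kw)


def write_pbn(pbn: ProbabilisticBooleanNetwork, path) -> None:
    Path(path).write_text(json.dumps(pbn_to_document(pbn), indent=1) + "\n")


def read_pbn(path) -> ProbabilisticBooleanNetwork:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError("$", f"not valid JSON: {exc}") from exc
    return document_to_pbn(doc)


def export_matrices(model: ControlledTransitionModel, out_dir, prefix: str = "A",
                    perturbed: bool = False) -> list[Path]:
    """Write one MatrixMarket file per control value; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mats = model.effective_matrices() if perturbed else model.matrices
    paths = []
    for u, A in enumerate(mats, start=1):
        path = out_dir / f"{prefix}_u{u}.mtx"
        scipy.io.mmwrite(path, sp.coo_matrix(A))
        paths.append(path)
    return paths
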