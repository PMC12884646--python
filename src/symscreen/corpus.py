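"""Corpora of short symptom statements and per-pair layer-score tables.

The unit of analysis throughout the package is a short clinical sentence
(a DSM-5 symptom statement or a questionnaire item) carrying an id, a
symptom-domain label and a source-instrument name.  The 18 core DSM-5
ADHD statements and the two published 36-pair layer-score tables are
bundled as package data and loadable by name.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

DOMAINS = ("inattention", "hyperactivity_impulsivity", "non_adhd", "unknown")

_BUNDLED = {
    "dsm5_adhd": "dsm5_adhd.csv",
    "table5_inattention": "table5_inattention.csv",
    "table6_hyperactivity": "table6_hyperactivity.csv",
}


class EmptyCorpusError(ValueError):
    """Raised when a corpus file or object contains no items."""


class CorpusFormatError(ValueError):
    """Raised for malformed corpus rows (blank text, duplicate ids...)."""


@dataclass(frozen=True)
class SymptomStatement:
    """One labelled short-text item (symptom statement or questionnaire item)."""

    id: str
    text: str
    domain: str = "unknown"
    source: str = ""

    def __post_init__(self) -> None:
        if not self.text or not self.text.strip():
            raise CorpusFormatError(f"statement {self.id!r} has blank text")
        if self.domain not in DOMAINS:
            raise CorpusFormatError(
                f"statement {self.id!r}: unknown domain {self.domain!r}; "
                f"expected one of {DOMAINS}"
            )


@dataclass(frozen=True)
class Corpus:
    """An ordered collection of :class:`SymptomStatement` with unique ids."""

    items: tuple[SymptomStatement, ...]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CorpusFormatError(f"duplicate ids in corpus: {dupes}")

    def __iter__(self) -> Iterator[SymptomStatement]:
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, i: int) -> SymptomStatement:
        return self.items[i]

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.items]

    @property
    def texts(self) -> list[str]:
        return [s.text for s in self.items]

    @property
    def labels(self) -> list[str]:
        return [s.domain for s in self.items]

    def subset(self, domain: str) -> "Corpus":
        """All items carrying the given domain label, order preserved."""
        return Corpus(tuple(s for s in self.items if s.domain == domain))

    def get(self, domain: str, index: int) -> SymptomStatement:
        """1-based lookup within a domain, matching published row numbers."""
        sub = self.subset(domain)
        if not 1 <= index <= len(sub):
            raise IndexError(f"{domain} has {len(sub)} items; asked for {index}")
        return sub[index - 1]

    @staticmethod
    def from_statements(items: Iterable[SymptomStatement]) -> "Corpus":
        return Corpus(tuple(items))


@dataclass(frozen=True)
class LayerScoreTable:
    """Per-pair similarity scores, rows = unordered symptom pairs, columns = layers.

    ``x`` holds the three layer columns in the fixed order
    (lexical, syntactic, semantic).  A reference ``combined`` column, when
    present in the source table, is kept separately and never enters the
    entropy-weight computation.
    """

    pair_labels: tuple[tuple[int, int], ...]
    x: np.ndarray  # shape (m, 3)
    layer_names: tuple[str, ...] = ("lexical", "syntactic", "semantic")
    combined_ref: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        if x.ndim != 2 or x.shape[1] != len(self.layer_names):
            raise ValueError(f"score matrix must be m x {len(self.layer_names)}")
        if len(self.pair_labels) != x.shape[0]:
            raise ValueError("pair_labels length must match row count")
        if not np.all(np.isfinite(x)):
            raise ValueError("all layer scores must be finite")
        if len(set(self.pair_labels)) != len(self.pair_labels):
            raise ValueError("duplicate pair labels")
        for a, b in self.pair_labels:
            if a >= b:
                raise ValueError(f"pair labels must be (low, high): ({a}, {b})")

    @property
    def m(self) -> int:
        return self.x.shape[0]

    @property
    def n(self) -> int:
        return self.x.shape[1]

    def column(self, layer: str) -> np.ndarray:
        return self.x[:, self.layer_names.index(layer)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.x, columns=list(self.layer_names))
        df.insert(0, "pair", [f"({a}, {b})" for a, b in self.pair_labels])
        if self.combined_ref is not None:
            df["combined"] = self.combined_ref
        return df


_PAIR_RE = re.compile(r"^\s*\(?\s*(\d+)\s*[,\-]\s*(\d+)\s*\)?\s*$")


def _parse_pair(label: str) -> tuple[int, int]:
    m = _PAIR_RE.match(str(label))
    if not m:
        raise ValueError(f"unparseable pair label: {label!r}")
    a, b = int(m.group(1)), int(m.group(2))
    return (min(a, b), max(a, b))


def read_score_table(path_or_buf) -> LayerScoreTable:
    """Read a layer-score CSV (columns: pair, lexical, syntactic, semantic[, combined])."""
    df = pd.read_csv(path_or_buf)
    required = {"pair", "lexical", "syntactic", "semantic"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    pairs = tuple(_parse_pair(p) for p in df["pair"])
    x = df[["lexical", "syntactic", "semantic"]].to_numpy(dtype=float)
    combined = df["combined"].to_numpy(dtype=float) if "combined" in df.columns else None
    return LayerScoreTable(pairs, x, combined_ref=combined)


def write_score_table(table: LayerScoreTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def _autogen_id(i: int) -> str:
    return f"{i:03d}"


def read_corpus(path, format: str | None = None) -> Corpus:
    """Read a corpus from ``csv``, ``json`` or ``txt_lines``.

    Rows must at least carry a ``text`` field (csv/json); a missing domain
    maps to ``unknown``; missing ids are autogenerated as zero-padded
    ordinals.  An empty file raises :class:`EmptyCorpusError`; a row with
    blank text is rejected with its row index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".csv": "csv", ".json": "json"}.get(path.suffix.lower(), "txt_lines")
    if format not in {"csv", "json", "txt_lines"}:
        raise ValueError(f"unknown corpus format {format!r}")

    raw: list[dict] = []
    if format == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "text" not in reader.fieldnames:
                if reader.fieldnames is None:
                    raise EmptyCorpusError(f"{path} is empty")
                raise CorpusFormatError(f"{path}: csv header must include 'text'")
            raw = list(reader)
    elif format == "json":
        content = path.read_text(encoding="utf-8").strip()
        if not content:
            raise EmptyCorpusError(f"{path} is empty")
        data = json.loads(content)
        if not isinstance(data, list):
            raise CorpusFormatError(f"{path}: json corpus must be an array of objects")
        raw = data
    else:  # txt_lines
        raw = [
            {"text": line}
            for line in path.read_text(encoding="utf-8").splitlines()
            if line.strip()
        ]

    if not raw:
        raise EmptyCorpusError(f"{path} contains no items")

    items = []
    for i, row in enumerate(raw):
        text = (row.get("text") or "").strip()
        if not text:
            raise CorpusFormatError(f"{path}: row {i} has blank text")
        items.append(
            SymptomStatement(
                id=str(row.get("id") or _autogen_id(i)),
                text=text,
                domain=row.get("domain") or "unknown",
                source=row.get("source") or "",
            )
        )
    return Corpus(tuple(items))


def write_corpus(corpus: Corpus, path, format: str | None = None) -> None:
    """Write a corpus so that :func:`read_corpus` round-trips it field-for-field."""
    if len(corpus) == 0:
        raise EmptyCorpusError("refusing to write an empty corpus")
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".json": "json"}.get(path.suffix.lower(), "txt_lines")
    if format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=["id", "text", "domain", "source"])
            writer.writeheader()
            for s in corpus:
                writer.writerow(
                    {"id": s.id, "text": s.text, "domain": s.domain, "source": s.source}
                )
    elif format == "json":
        payload = [
            {"id": s.id, "text": s.text, "domain": s.domain, "source": s.source}
            for s in corpus
        ]
        path.write_text(
            json.dumps(payload, ensure_ascii=False, indent=1), encoding="utf-8"
        )
    elif format == "txt_lines":
        path.write_text("\n".join(s.text for s in corpus) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown corpus format {format!r}")


def _data_text(filename: str) -> str:
    return resources.files("symscreen.data").joinpath(filename).read_text(
        encoding="utf-8"
    )


def load_bundled(name: str):
    """Load a bundled resource by name.

    ``dsm5_adhd`` returns the 18-statement :class:`Corpus` exactly as
    published (9 inattention + 9 hyperactivity/impulsivity);
    ``table5_inattention`` / ``table6_hyperactivity`` return the 36-row
    :class:`LayerScoreTable` for the corresponding domain, with the
    published combined column retained as reference data.
    """
    if name not in _BUNDLED:
        raise KeyError(
            f"unknown bundled resource {name!r}; valid names: {sorted(_BUNDLED)}"
        )
    text = _data_text(_BUNDLED[name])
    if name == "dsm5_adhd":
        buf = io.StringIO(text)
        reader = csv.DictReader(buf)
        return Corpus(
            tuple(
                SymptomStatement(
                    id=row["id"],
                    text=row["text"],
                    domain=row["domain"],
                    source=row["source"],
                )
                for row in reader
            )
        )
    return read_score_table(io.StringIO(text))
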