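"""Corpus and token-stream input/output.

A corpus is either a directory of UTF-8 ``.txt`` files (file stem = document
id) or a JSON-lines file with objects ``{"id", "text", "treatments": [...]}``.
Token streams round-trip through JSON lines.
"""

from __future__ import annotations

import json
from pathlib import Path

from .textprep import RawLetter, Token, TokenKind, TokenStream


def read_corpus(path) -> tuple[list[RawLetter], dict[str, list[str]]]:
    """Return (letters, labels); labels maps doc id -> treatment codes."""
    path = Path(path)
    letters: list[RawLetter] = []
    labels: dict[str, list[str]] = {}
    if path.is_dir():
        for f in sorted(path.glob("*.txt")):
            letters.append(RawLetter(f.stem, f.read_text("utf-8")))
    else:
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                rec = json.loads(line)
                letters.append(RawLetter(str(rec["id"]), rec["text"]))
                if "treatments" in rec:
                    labels[str(rec["id"])] = list(rec["treatments"])
    ids = [l.id for l in letters]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate document ids in corpus")
    return letters, labels


def write_corpus(path, letters, labels=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for letter in letters:
            rec = {"id": letter.id, "text": letter.text}
            if labels and letter.id in labels:
                rec["treatments"] = labels[letter.id]
            fh.write(json.dumps(rec) + "\n")


def write_streams(path, streams) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in streams:
            rec = {
                "id": s.doc_id,
                "tokens": [[t.surface, t.kind.value, t.span[0], t.span[1]] for t in s.tokens],
                "sentence_breaks": s.sentence_breaks,
            }
            fh.write(json.dumps(rec) + "\n")


def read_streams(path) -> list[TokenStream]:
    streams = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            tokens = [
                Token(surface, TokenKind(kind), (start, end))
                for surface, kind, start, end in rec["tokens"]
            ]
            streams.append(
                TokenStream(str(rec["id"]), tokens, rec.get("sentence_breaks", []))
            )
    return streams
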