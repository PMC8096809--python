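"""Readers and writers for the on-disk exchange formats.

Notes travel as JSON-lines (one object per note with patient_id, note_id,
ISO-8601 timestamp, text); outcomes and weak scores as CSV; word lists as
one-entry-per-line text files. Synthetic and real corpora use the same
formats, so the two paths are interchangeable.
"""

from __future__ import annotations

import json
from datetime import date
from typing import Iterable

import pandas as pd

from .preprocess import RawNote
from .timeline import WeakScoreTable

__all__ = [
    "read_notes_jsonl",
    "write_notes_jsonl",
    "read_outcomes_csv",
    "write_outcomes_csv",
    "read_weak_scores_csv",
    "write_weak_scores_csv",
    "read_wordlist",
    "write_wordlist",
]


def write_notes_jsonl(notes: Iterable[RawNote], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for n in notes:
            fh.write(
                json.dumps(
                    {
                        "patient_id": n.patient_id,
                        "note_id": n.note_id,
                        "timestamp": n.timestamp.isoformat(),
                        "text": n.text,
                    }
                )
                + "\n"
            )


def read_notes_jsonl(path) -> list[RawNote]:
    notes = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            nid = str(obj["note_id"])
            if nid in seen:
                raise ValueError(f"duplicate note_id {nid!r}")
            seen.add(nid)
            notes.append(
                RawNote(
                    patient_id=str(obj["patient_id"]),
                    note_id=nid,
                    timestamp=date.fromisoformat(obj["timestamp"]),
                    text=str(obj["text"]),
                )
            )
    return notes


def write_outcomes_csv(
    recurrence_date: dict[str, date | None], label_source: dict[str, str], path
) -> None:
    rows = [
        {
            "patient_id": pid,
            "recurrence_date": d.isoformat() if d is not None else "",
            "label_source": label_source.get(pid, "manual"),
        }
        for pid, d in sorted(recurrence_date.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_outcomes_csv(path) -> tuple[dict[str, date | None], dict[str, str]]:
    df = pd.read_csv(path, dtype={"patient_id": str, "label_source": str})
    rec: dict[str, date | None] = {}
    src: dict[str, str] = {}
    for row in df.itertuples(index=False):
        d = getattr(row, "recurrence_date")
        rec[row.patient_id] = (
            date.fromisoformat(str(d)) if isinstance(d, str) and d else None
        )
        src[row.patient_id] = row.label_source
    return rec, src


def write_weak_scores_csv(scores: WeakScoreTable, path) -> None:
    pd.DataFrame(
        [{"note_id": nid, "score": s} for nid, s in sorted(scores.score.items())]
    ).to_csv(path, index=False)


def read_weak_scores_csv(path) -> WeakScoreTable:
    df = pd.read_csv(path, dtype={"note_id": str})
    return WeakScoreTable({r.note_id: float(r.score) for r in df.itertuples(index=False)})


def read_wordlist(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_wordlist(words: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for w in words:
            fh.write(w + "\n")
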