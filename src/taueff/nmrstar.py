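"""Minimal NMR-STAR 3.1 reading for heteronuclear T₂/R₂ save-frames.

Implements just enough of the STAR grammar — data blocks, save-frames,
free tags, loops, quoted and semicolon-delimited values, comments — to
extract per-residue transverse relaxation lists in the BMRB dialect
(``_Heteronucl_T2_list`` / ``_T2`` tags).  This is not a general STAR
library; chemical shift lists, entities etc. are parsed structurally
but ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

__all__ = ["Saveframe", "Loop", "parse_star", "read_star_file"]

_NULLS = {".", "?", ""}


@dataclass
class Loop:
    tags: List[str] = field(default_factory=list)
    rows: List[List[str]] = field(default_factory=list)

    def column(self, suffix: str) -> Optional[int]:
        """Index of the first tag whose name ends with ``.suffix`` (case-insensitive)."""
        want = suffix.lower()
        for i, tag in enumerate(self.tags):
            if tag.lower().endswith("." + want):
                return i
        return None


@dataclass
class Saveframe:
    name: str
    tags: Dict[str, str] = field(default_factory=dict)
    loops: List[Loop] = field(default_factory=list)

    def get(self, suffix: str) -> Optional[str]:
        """Value of the first free tag whose name ends with ``.suffix``."""
        want = suffix.lower()
        for tag, value in self.tags.items():
            if tag.lower().endswith("." + want):
                return None if value in _NULLS else value
        return None


def _tokenize(text: str):
    """Yield STAR tokens: handles #-comments, '…', "…" and ;-delimited text."""
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith(";"):
            # semicolon-delimited value: runs until the next line starting ';'
            chunk: List[str] = []
            i += 1
            while i < len(lines) and not lines[i].startswith(";"):
                chunk.append(lines[i])
                i += 1
            i += 1
            yield "\n".join(chunk)
            continue
        pos = 0
        n = len(line)
        while pos < n:
            while pos < n and line[pos] in " \t":
                pos += 1
            if pos >= n or line[pos] == "#":
                break
            if line[pos] in "'\"":
                quote = line[pos]
                end = pos + 1
                # closing quote must be followed by whitespace or EOL
                while end < n:
                    if line[end] == quote and (end + 1 == n
                                               or line[end + 1] in " \t"):
                        break
                    end += 1
                if end >= n:
                    raise ValueError(f"unterminated quote in line: {line!r}")
                yield line[pos + 1:end]
                pos = end + 1
            else:
                m = re.match(r"\S+", line[pos:])
                yield m.group(0)
                pos += m.end()
        i += 1


def parse_star(text: str) -> List[Saveframe]:
    """Parse NMR-STAR text into a flat list of save-frames."""
    frames: List[Saveframe] = []
    current: Optional[Saveframe] = None
    tokens = _tokenize(text)
    pending_tag: Optional[str] = None
    try:
        while True:
            tok = next(tokens, None)
            if tok is None:
                break
            low = tok.lower()
            if low.startswith("data_"):
                continue
            if low == "save_":
                current = None
                continue
            if low.startswith("save_"):
                current = Saveframe(name=tok[5:])
                frames.append(current)
                continue
            if low == "loop_":
                loop = Loop()
                # tag header
                tok = next(tokens, None)
                while tok is not None and tok.startswith("_"):
                    loop.tags.append(tok)
                    tok = next(tokens, None)
                # values until stop_
                values: List[str] = []
                while tok is not None and tok.lower() != "stop_":
                    values.append(tok)
                    tok = next(tokens, None)
                ncol = len(loop.tags)
                if ncol and len(values) % ncol == 0:
                    loop.rows = [values[j:j + ncol]
                                 for j in range(0, len(values), ncol)]
                elif ncol:
                    raise ValueError(
                        f"loop with {ncol} tags has {len(values)} values "
                        "(not a multiple)"
                    )
                if current is not None:
                    current.loops.append(loop)
                continue
            if tok.startswith("_"):
                pending_tag = tok
                value = next(tokens, None)
                if value is None:
                    raise ValueError(f"tag {pending_tag} has no value")
                if current is not None:
                    current.tags[pending_tag] = value
                pending_tag = None
                continue
            # stray value outside any structure: ignore
    except StopIteration:  # pragma: no cover - defensive
        pass
    return frames


def read_star_file(path) -> List[Saveframe]:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_star(fh.read())


def find_t2_saveframes(frames: List[Saveframe]) -> List[Saveframe]:
    """Save-frames that carry a heteronuclear T₂/R₂ relaxation list."""
    hits = []
    for frame in frames:
        category = (frame.get("Sf_category") or "").lower()
        has_t2_loop = any(
            tag.lower().startswith(("_t2.", "_heteronucl_t2"))
            for loop in frame.loops for tag in loop.tags
        )
        if "heteronucl_t2" in category or has_t2_loop:
            hits.append(frame)
    return hits


def extract_t2_rows(frame: Saveframe
                    ) -> Tuple[Optional[float], str, List[dict]]:
    """Extract (spectrometer_MHz, value_kind, rows) from a T₂ save-frame.

    ``value_kind`` is ``"T2"`` (seconds; convert to R₂ = 1/T₂) or
    ``"R2"`` (already a rate).  Each row dict has keys ``seq``,
    ``comp``, ``value``, ``err`` (err may be None).
    """
    freq_text = frame.get("Spectrometer_frequency_1H")
    freq = float(freq_text) if freq_text is not None else None

    units = (frame.get("T2_val_units") or "").lower()
    loop = None
    for cand in frame.loops:
        if any(t.lower().startswith("_t2.") for t in cand.tags):
            loop = cand
            break
    if loop is None:
        raise ValueError(f"save-frame {frame.name!r} has no _T2 loop")

    val_col = None
    kind = "T2"
    for suffix, k in (("T2_val", "T2"), ("R2_val", "R2"), ("Val", "T2")):
        val_col = loop.column(suffix)
        if val_col is not None:
            kind = k
            break
    if val_col is None:
        raise ValueError(f"save-frame {frame.name!r}: no T2/R2 value column")
    if units in ("s-1", "1/s", "s^-1", "hz"):
        kind = "R2"
    elif units in ("s", "sec", "seconds", "ms"):
        kind = "T2"

    seq_col = loop.column("Comp_index_ID")
    if seq_col is None:
        seq_col = loop.column("Seq_ID")
    comp_col = loop.column("Comp_ID")
    err_col = loop.column("T2_val_err")
    if err_col is None:
        err_col = loop.column("Val_err")
    if err_col is None:
        err_col = loop.column("R2_val_err")
    if seq_col is None:
        raise ValueError(
            f"save-frame {frame.name!r}: no residue index column"
        )

    scale = 1e-3 if units == "ms" else 1.0
    rows = []
    for raw in loop.rows:
        value = raw[val_col]
        if value in _NULLS:
            continue
        err = None
        if err_col is not None and raw[err_col] not in _NULLS:
            err = float(raw[err_col]) * (scale if kind == "T2" else 1.0)
        rows.append({
            "seq": int(raw[seq_col]),
            "comp": (raw[comp_col] if comp_col is not None
                     and raw[comp_col] not in _NULLS else None),
            "value": float(value) * (scale if kind == "T2" else 1.0),
            "err": err,
        })
    return freq, kind, rows


def write_synthetic_t2_star(path, entries, entry_id: str = "synthetic") -> None:
    """Write a synthetic NMR-STAR file with T₂ save-frames (test fixture).

    ``entries`` is a list of (spectrometer_MHz | None, rows) pairs with
    rows as produced by :func:`extract_t2_rows`; values are T₂ in
    seconds.  Output mimics the BMRB 3.1 heteronuclear T₂ dialect.
    """
    lines = [f"data_{entry_id}", ""]
    for idx, (freq, rows) in enumerate(entries, start=1):
        lines += [
            f"save_heteronucl_T2_list_{idx}",
            "   _Heteronucl_T2_list.Sf_category    heteronucl_T2_relaxation",
            f"   _Heteronucl_T2_list.ID             {idx}",
            "   _Heteronucl_T2_list.T2_val_units   s",
        ]
        if freq is not None:
            lines.append(
                f"   _Heteronucl_T2_list.Spectrometer_frequency_1H  {freq:g}"
            )
        lines += [
            "   loop_",
            "      _T2.Comp_index_ID",
            "      _T2.Comp_ID",
            "      _T2.T2_val",
            "      _T2.T2_val_err",
        ]
        for row in rows:
            err = row.get("err")
            lines.append(
                f"      {row['seq']} {row.get('comp') or '.'} "
                f"{row['value']:.6g} {err if err is not None else '.'}"
            )
        lines += ["   stop_", "save_", ""]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))
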