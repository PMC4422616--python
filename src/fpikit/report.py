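"""Report rendering: color-coded score tables and group profiles.

Renders a score table as a heatmap-style grid — cases as rows sorted
descending by a chosen node (ties broken by case_id), nodes as columns,
each cell carrying the score and its red/yellow/green performance bin.
Output is a pure function of its inputs: identical tables render to
byte-identical text or single-file HTML (inline styles only).
"""

from __future__ import annotations

import pandas as pd

from .aggregation import ScoreTable

__all__ = ["render_heatmap_table", "render_group_profile"]

_HTML_COLORS = {"green": "#4caf50", "yellow": "#ffeb3b", "red": "#ef5350", "": "#eeeeee"}
_ABBREV = {"green": "G", "yellow": "Y", "red": "R", "": " "}


def _sorted_pivot(table: ScoreTable, sort_node: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    frame = table.frame
    if sort_node not in set(frame["node_id"]):
        raise KeyError(f"unknown sort node {sort_node!r}")
    scores = frame.pivot(index="case_id", columns="node_id", values="score")
    colors = frame.pivot(index="case_id", columns="node_id", values="color")
    # column order follows first appearance in the long frame (schema order)
    cols = list(dict.fromkeys(frame["node_id"]))
    scores, colors = scores[cols], colors[cols]
    order = sorted(
        scores.index,
        key=lambda cid: (
            -(scores.at[cid, sort_node] if pd.notna(scores.at[cid, sort_node]) else float("-inf")),
            cid,
        ),
    )
    return scores.loc[order], colors.loc[order]


def render_heatmap_table(table: ScoreTable, sort_node: str, fmt: str = "text") -> str:
    """Render the table sorted by ``sort_node``; ``fmt`` is text or html.

    MISSING cells render blank, never as zeros.
    """
    scores, colors = _sorted_pivot(table, sort_node)
    if fmt == "text":
        return _render_text(scores, colors)
    if fmt == "html":
        return _render_html(scores, colors)
    raise ValueError(f"unknown format {fmt!r}")


def _cell(score, color) -> str:
    if pd.isna(score):
        return ""
    return f"{score:.2f} {_ABBREV[color]}"


def _render_text(scores: pd.DataFrame, colors: pd.DataFrame) -> str:
    cols = list(scores.columns)
    width = {c: max(len(c), 7) for c in cols}
    idw = max([len("case_id")] + [len(i) for i in scores.index])
    lines = ["  ".join(["case_id".ljust(idw)] + [c.rjust(width[c]) for c in cols])]
    for cid in scores.index:
        cells = [
            _cell(scores.at[cid, c], colors.at[cid, c]).rjust(width[c]) for c in cols
        ]
        lines.append("  ".join([cid.ljust(idw)] + cells))
    return "\n".join(lines) + "\n"


def _render_html(scores: pd.DataFrame, colors: pd.DataFrame) -> str:
    rows = []
    header = "".join(f"<th>{c}</th>" for c in scores.columns)
    rows.append(f"<tr><th>case_id</th>{header}</tr>")
    for cid in scores.index:
        cells = []
        for c in scores.columns:
            s, col = scores.at[cid, c], colors.at[cid, c]
            bg = _HTML_COLORS[col if isinstance(col, str) else ""]
            text = "" if pd.isna(s) else f"{s:.2f}"
            cells.append(f'<td style="background:{bg};text-align:right">{text}</td>')
        rows.append(f"<tr><td>{cid}</td>{''.join(cells)}</tr>")
    body = "\n".join(rows)
    return (
        '<table style="border-collapse:collapse;font-family:sans-serif">\n'
        f"{body}\n</table>\n"
    )


def render_group_profile(profile: pd.DataFrame, title: str = "") -> str:
    """Plain-text rendering of a dimension x group mean table."""
    header = f"{title}\n" if title else ""
    return header + profile.round(3).to_string() + "\n"
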