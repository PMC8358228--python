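"""Membrane-attachment motif checks and predictor-consensus calls.

Small GTPases of the ARF family attach to membranes through N-terminal
myristoylation (requires Gly at position 2, after initiator-Met cleavage; an
alternative N-myristoyltransferase activity can acylate Lys at position 3),
S-palmitoylation of cysteines near the N-terminus, C-terminal prenylation
(CaaX motif: Cys fourth from the C-terminus), or an N-terminal amphipathic/
transmembrane helix. The sequence-intrinsic checks here are purely
positional; lipidation-site predictions come from external tools whose
outputs are combined by a k-of-n consensus rule (at least 2 of 3 tools for
myristoylation, at least 3 of 5 for palmitoylation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "MotifReport",
    "ConsensusCall",
    "scan_nterm_motifs",
    "caax_scan",
    "consensus_call",
    "consensus_from_table",
    "group_feature_summary",
    "MYRISTOYLATION_MIN_TOOLS",
    "PALMITOYLATION_MIN_TOOLS",
]

MYRISTOYLATION_MIN_TOOLS = 2
PALMITOYLATION_MIN_TOOLS = 3
DEFAULT_NTERM_WINDOW = 25


@dataclass
class MotifReport:
    seq_id: str
    gly2: bool
    lys3: bool
    nterm_cys: list[int] = field(default_factory=list)
    caax: bool = False
    terminal_4mer: str = ""


@dataclass
class ConsensusCall:
    """k-of-n consensus over per-tool boolean calls for one site."""

    modification: str
    site: str
    tool_calls: dict[str, bool]
    k: int
    verdict: bool = field(init=False)

    def __post_init__(self):
        if not self.tool_calls:
            raise ValueError("consensus requires at least one tool call")
        self.verdict = sum(self.tool_calls.values()) >= self.k


def scan_nterm_motifs(seq, window: int = DEFAULT_NTERM_WINDOW) -> MotifReport:
    """Positional N-terminal motif checks (1-based positions).

    gly2: Gly at position 2 (the myristoylation prerequisite); lys3: Lys at
    position 3; nterm_cys: cysteine positions within the N-terminal window
    (candidate palmitoylation sites).
    """
    seq_id = getattr(seq, "id", "")
    residues = getattr(seq, "ungapped", None) or (seq if isinstance(seq, str) else seq.residues)
    residues = residues.upper().replace("-", "")
    if len(residues) < 3:
        raise ValueError(f"sequence {seq_id!r} shorter than 3 residues")
    report = MotifReport(
        seq_id=seq_id,
        gly2=residues[1] == "G",
        lys3=residues[2] == "K",
        nterm_cys=[i for i, c in enumerate(residues[:window], start=1) if c == "C"],
    )
    if len(residues) >= 4:
        report.caax = residues[-4] == "C"
        report.terminal_4mer = residues[-4:]
    return report


def caax_scan(seq) -> tuple[bool, str]:
    """CaaX check: Cys fourth from the C-terminus. Returns (hit, terminal
    4-mer); the two 'a' positions and X are reported, not constrained."""
    residues = getattr(seq, "ungapped", None) or (seq if isinstance(seq, str) else seq.residues)
    residues = residues.upper().replace("-", "")
    if len(residues) < 4:
        return False, residues
    return residues[-4] == "C", residues[-4:]


def consensus_call(
    calls: dict[str, bool | None],
    k: int,
    modification: str = "",
    site: str = "",
    missing_policy: str = "negative",
) -> ConsensusCall:
    """Combine per-tool calls by the at-least-k rule.

    ``missing_policy="negative"`` counts tools without output as negative
    (the literal reading of "predicted by at least k tools");
    ``"renormalize"`` instead shrinks k proportionally to the tools present.
    """
    if not calls:
        raise ValueError("no tool calls supplied")
    present = {t: v for t, v in calls.items() if v is not None}
    if missing_policy == "negative":
        effective = {t: (False if v is None else bool(v)) for t, v in calls.items()}
        k_eff = k
    elif missing_policy == "renormalize":
        if not present:
            raise ValueError("all tool calls missing under renormalize policy")
        effective = present
        k_eff = max(1, round(k * len(present) / len(calls)))
    else:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    return ConsensusCall(modification=modification, site=site,
                         tool_calls=effective, k=k_eff)


def consensus_from_table(
    calls: pd.DataFrame,
    modification: str,
    k: int,
    tools: list[str] | None = None,
    missing_policy: str = "negative",
) -> pd.DataFrame:
    """Per-(seq_id, site) consensus verdicts from a predictor_calls table.

    ``tools`` fixes the tool panel (so a tool silent on a site counts per the
    missing policy); by default the panel is every tool appearing for the
    modification anywhere in the table.
    """
    sub = calls[calls["modification"] == modification]
    if tools is None:
        tools = sorted(sub["tool"].unique())
    if not tools:
        raise ValueError(f"no tools found for modification {modification!r}")
    rows = []
    for (seq_id, site), grp in sub.groupby(["seq_id", "site"], sort=True):
        observed = dict(zip(grp["tool"], grp["call"]))
        per_tool = {t: observed.get(t) for t in tools}
        cc = consensus_call(per_tool, k, modification=modification, site=site,
                            missing_policy=missing_policy)
        rows.append({"seq_id": seq_id, "site": site,
                     "n_positive": sum(cc.tool_calls.values()),
                     "n_tools": len(tools), "verdict": cc.verdict})
    return pd.DataFrame(rows, columns=["seq_id", "site", "n_positive", "n_tools", "verdict"])


def group_feature_summary(
    labels: dict[str, str],
    motif_reports: dict[str, MotifReport],
    myr_positive: set,
    palm_positive: set,
    tm_positive: set,
    highlight_threshold: float = 50.0,
) -> pd.DataFrame:
    """Per-paralog percentages of membrane-attachment features.

    One row per paralog label: sequence count, %Gly2, %myristoylation
    consensus, %palmitoylation consensus, %TM-predicted, and a flag for
    values above the highlight threshold (default 50%).
    """
    if not labels:
        raise ValueError("no labelled sequences")
    by_label: dict[str, list[str]] = {}
    for seq_id, label in labels.items():
        by_label.setdefault(label, []).append(seq_id)
    rows = []
    for label in sorted(by_label):
        members = by_label[label]
        if not members:
            raise ValueError(f"empty label group {label!r}")
        n = len(members)
        pct = lambda hit: 100.0 * sum(hit(s) for s in members) / n  # noqa: E731
        row = {
            "label": label,
            "n": n,
            "pct_gly2": pct(lambda s: motif_reports[s].gly2),
            "pct_myr": pct(lambda s: s in myr_positive),
            "pct_palm": pct(lambda s: s in palm_positive),
            "pct_tm": pct(lambda s: s in tm_positive),
        }
        row["highlighted"] = ";".join(
            c for c in ("pct_gly2", "pct_myr", "pct_palm", "pct_tm")
            if row[c] > highlight_threshold
        )
        rows.append(row)
    return pd.DataFrame(rows)
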