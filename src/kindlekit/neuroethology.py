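"""Sequential behavioral analysis: frequencies, durations, dyads, flowcharts.

Behavior is coded second by second from a fixed glossary of codes (sniffing
SN, walking WA, grooming-of-face GRF, rearing REAR, ...).  Maximal runs of
one code are *bouts*; per observation period the analysis reports each
code's frequency (bout count), mean bout duration, and proportional time.

The sequential structure is tested dyad by dyad: for every ordered pair of
codes (A, B), all bout-to-bout transitions in the period are cross
classified into the 2x2 table {A->B, A->not-B, not-A->B, not-A->not-B} and
the Pearson chi-square on that table (expected counts from the marginals)
measures the association between "transition leaves A" and "transition
enters B".  A dyad is flagged significant — it becomes an arrow of the
flowchart — when

    chi2 >= 3.84  and  log10(chi2) >= 0.25  and  observed > expected,

i.e. the two published thresholds (3.84 is the 95th percentile of
chi-square with 1 df) plus the attraction condition: only couplings that
*facilitate* the second behavior draw arrows.  Self-transitions cannot
occur by construction (a run of one code is a single bout), matching
flowcharts that never show self-loops.  No multiple-testing correction is
applied across dyads by default (the fixed per-dyad threshold is the
published procedure); a Bonferroni flag is provided.

Flowcharts render each behavior as a rectangle whose height encodes
frequency and base encodes mean duration, colored by behavioral category
(exploratory, grooming, limbic, fear/aversion, procursive, other), with
arrows for significant dyads whose width encodes interaction strength and
whose color follows the source behavior's category.  One subgraph cell per
period, in PRE -> STIMULUS -> POST order.
"""

from __future__ import annotations

import json
import math
import re
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import yaml
from scipy import stats

__all__ = [
    "CHI2_CRITICAL",
    "LOG_CHI2_CRITICAL",
    "BehaviorSequence",
    "BehaviorSummary",
    "DyadStatistic",
    "FlowchartGraph",
    "bouts",
    "summarize",
    "summarize_pooled",
    "dyad_interactions",
    "dyad_interactions_pooled",
    "build_flowchart",
    "export_flowchart",
    "parse_dot",
    "flowchart_from_json",
    "validate_flowchart_json",
    "load_category_map",
    "default_category_map",
]

#: Critical chi-square (df=1) at alpha = 0.05 — the 95th-percentile quantile.
CHI2_CRITICAL = 3.84
#: Companion threshold on log10(chi2).
LOG_CHI2_CRITICAL = 0.25

_CATEGORY_COLORS = {
    "exploratory": "#2b8cbe",
    "grooming": "#31a354",
    "limbic": "#e34a33",
    "fear/aversion": "#ff8c00",
    "procursive": "#756bb1",
    "other": "#969696",
}

_PERIOD_ORDER = {"PRE": 0, "STIMULUS": 1, "POST": 2}


@dataclass(frozen=True)
class BehaviorSequence:
    """Second-by-second behavior codes for one animal, stimulus, and period."""

    animal_id: str
    stimulus_index: int
    period: str
    events: tuple[tuple[int, str], ...]  # (t_s, code), t strictly increasing

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(b - a != 1 for a, b in zip(times, times[1:])):
            raise ValueError(
                "behavior coding must be gapless at 1 s resolution; "
                "configure an explicit 'uncoded' filler code for gaps"
            )

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(code for _, code in self.events)

    @classmethod
    def from_codes(
        cls, codes: Sequence[str], animal_id: str = "a0", stimulus_index: int = 1,
        period: str = "PRE", t0: int = 0,
    ) -> "BehaviorSequence":
        return cls(
            animal_id=animal_id,
            stimulus_index=stimulus_index,
            period=period,
            events=tuple((t0 + i, c) for i, c in enumerate(codes)),
        )


@dataclass(frozen=True)
class Bout:
    code: str
    start_s: int
    duration_s: int


@dataclass(frozen=True)
class BehaviorSummary:
    """Per-code frequency / mean duration / proportional time for one period."""

    period_length_s: int
    frequency: Mapping[str, int]
    mean_duration_s: Mapping[str, float]
    proportional_time: Mapping[str, float]


@dataclass(frozen=True)
class DyadStatistic:
    """Association statistic for one ordered behavior pair (A -> B)."""

    pre_code: str
    post_code: str
    observed: int
    expected: float
    chi2: float  # NaN when a zero margin leaves it undefined
    log_chi2: float
    significant: bool


def bouts(seq: BehaviorSequence) -> list[Bout]:
    """Maximal runs of one code."""
    out: list[Bout] = []
    for t, code in seq.events:
        if out and out[-1].code == code and out[-1].start_s + out[-1].duration_s == t:
            out[-1] = Bout(code, out[-1].start_s, out[-1].duration_s + 1)
        else:
            out.append(Bout(code, t, 1))
    return out


def summarize(seq: BehaviorSequence) -> BehaviorSummary:
    """Frequency, mean bout duration, and proportional time per code."""
    if not seq.events:
        raise ValueError("cannot summarize an empty behavior sequence")
    runs = bouts(seq)
    total_s = len(seq.events)
    freq: dict[str, int] = {}
    dur: dict[str, int] = {}
    for b in runs:
        freq[b.code] = freq.get(b.code, 0) + 1
        dur[b.code] = dur.get(b.code, 0) + b.duration_s
    return BehaviorSummary(
        period_length_s=total_s,
        frequency=freq,
        mean_duration_s={c: dur[c] / freq[c] for c in freq},
        proportional_time={c: dur[c] / total_s for c in freq},
    )


def summarize_pooled(seqs: Sequence[BehaviorSequence]) -> BehaviorSummary:
    """Group-level summary: bout counts and durations pooled over animals.

    Mean duration is total seconds over total bouts per code; proportional
    time is over the pooled observation time.
    """
    if not seqs:
        raise ValueError("cannot summarize an empty collection of sequences")
    total_s = 0
    freq: dict[str, int] = {}
    dur: dict[str, int] = {}
    for seq in seqs:
        total_s += len(seq.events)
        for b in bouts(seq):
            freq[b.code] = freq.get(b.code, 0) + 1
            dur[b.code] = dur.get(b.code, 0) + b.duration_s
    return BehaviorSummary(
        period_length_s=total_s,
        frequency=freq,
        mean_duration_s={c: dur[c] / freq[c] for c in freq},
        proportional_time={c: dur[c] / total_s for c in freq},
    )


def _dyads_from_transitions(
    transitions: Sequence[tuple[str, str]],
    chi2_threshold: float,
    log_chi2_min: float,
    bonferroni: bool,
) -> list[DyadStatistic]:
    n = len(transitions)
    starts: dict[str, int] = {}
    ends: dict[str, int] = {}
    pair_counts: dict[tuple[str, str], int] = {}
    for a, b in transitions:
        starts[a] = starts.get(a, 0) + 1
        ends[b] = ends.get(b, 0) + 1
        pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
    if bonferroni:
        alpha = stats.chi2.sf(chi2_threshold, df=1) / max(1, len(pair_counts))
        chi2_threshold = float(stats.chi2.isf(alpha, df=1))
    out: list[DyadStatistic] = []
    for (a, b), observed in sorted(pair_counts.items()):
        row_a = starts[a]
        col_b = ends[b]
        chi2, expected = _dyad_chi2(
            observed, row_a - observed, col_b - observed, n - row_a - col_b + observed
        )
        log_chi2 = math.log10(chi2) if chi2 > 0 else float("-inf")
        significant = (
            math.isfinite(chi2)
            and chi2 >= chi2_threshold
            and log_chi2 >= log_chi2_min
            and observed > expected
        )
        out.append(
            DyadStatistic(
                pre_code=a, post_code=b, observed=observed,
                expected=float(expected), chi2=chi2,
                log_chi2=log_chi2, significant=significant,
            )
        )
    return out


def dyad_interactions_pooled(
    seqs: Sequence[BehaviorSequence],
    *,
    chi2_min: float = CHI2_CRITICAL,
    log_chi2_min: float = LOG_CHI2_CRITICAL,
    bonferroni: bool = False,
) -> list[DyadStatistic]:
    """Dyad statistics over transitions pooled from several animals' sequences.

    Transitions never cross animal boundaries.
    """
    transitions: list[tuple[str, str]] = []
    for seq in seqs:
        runs = bouts(seq)
        transitions.extend((a.code, b.code) for a, b in zip(runs, runs[1:]))
    if not transitions:
        return []
    return _dyads_from_transitions(transitions, chi2_min, log_chi2_min, bonferroni)


def _dyad_chi2(a_to_b: int, a_to_other: int, other_to_b: int, other_to_other: int
               ) -> tuple[float, float]:
    """(chi2, expected A->B) for a dyad 2x2; chi2 is NaN on a zero margin."""
    n = a_to_b + a_to_other + other_to_b + other_to_other
    row_a = a_to_b + a_to_other
    col_b = a_to_b + other_to_b
    if n == 0 or row_a == 0 or col_b == 0 or row_a == n or col_b == n:
        return float("nan"), float("nan") if n == 0 else row_a * col_b / n
    expected = row_a * col_b / n
    det = a_to_b * other_to_other - a_to_other * other_to_b
    chi2 = n * det * det / (row_a * (n - row_a) * col_b * (n - col_b))
    return float(chi2), float(expected)


def dyad_interactions(
    seq: BehaviorSequence,
    *,
    chi2_min: float = CHI2_CRITICAL,
    log_chi2_min: float = LOG_CHI2_CRITICAL,
    bonferroni: bool = False,
) -> list[DyadStatistic]:
    """Dyadic-association statistics over all observed bout transitions.

    Every ordered pair (A, B) with at least one observed A->B transition is
    reported.  Significance requires both published thresholds and observed
    count above expectation (attraction).  With ``bonferroni`` the chi-square
    threshold is raised to the Bonferroni-adjusted chi-square(1) quantile for
    the number of dyads tested.
    """
    runs = bouts(seq)
    if len(runs) < 2:
        return []
    transitions = [(a.code, b.code) for a, b in zip(runs, runs[1:])]
    return _dyads_from_transitions(transitions, chi2_min, log_chi2_min, bonferroni)


# ---------------------------------------------------------------------------
# Flowchart graphs


@dataclass(frozen=True)
class FlowchartNode:
    code: str
    period: str
    height: float  # proportional to frequency
    base: float    # proportional to mean bout duration
    category: str
    color: str


@dataclass(frozen=True)
class FlowchartEdge:
    pre_code: str
    post_code: str
    period: str
    width: float  # proportional to chi2 (interaction strength)
    color: str    # source node's category color


@dataclass
class FlowchartGraph:
    """Deterministic flowchart: one cell per period, nodes + significant dyads."""

    periods: tuple[str, ...]
    nodes: tuple[FlowchartNode, ...]
    edges: tuple[FlowchartEdge, ...]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FlowchartGraph):
            return NotImplemented
        return (
            self.periods == other.periods
            and self.nodes == other.nodes
            and self.edges == other.edges
        )


#: Node-geometry clamps (dimensionless drawing units).
_MIN_SIZE, _MAX_SIZE = 0.3, 3.0


def _scale(value: float, max_value: float) -> float:
    if max_value <= 0:
        return _MIN_SIZE
    return _MIN_SIZE + (_MAX_SIZE - _MIN_SIZE) * min(1.0, value / max_value)


def default_category_map() -> dict[str, str]:
    path = Path(__file__).parent / "data" / "behavior_categories.yaml"
    return load_category_map(path)


def load_category_map(path: str | Path) -> dict[str, str]:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    out: dict[str, str] = {}
    for category, codes in raw.items():
        if category not in _CATEGORY_COLORS:
            raise ValueError(
                f"unknown behavioral category {category!r}; "
                f"expected one of {sorted(_CATEGORY_COLORS)}"
            )
        for code in codes:
            out[str(code)] = category
    return out


def build_flowchart(
    summaries: Mapping[str, BehaviorSummary],
    dyads: Mapping[str, Sequence[DyadStatistic]],
    category_map: Mapping[str, str] | None = None,
    *,
    drop_zero_frequency: bool = True,
) -> FlowchartGraph:
    """Assemble the flowchart from per-period summaries and dyad lists.

    ``summaries`` / ``dyads`` map period name -> data.  Node height scales
    with frequency and base with mean duration (linear, clamped to
    [0.3, 3.0] drawing units relative to the period maximum); only
    significant dyads become edges.  Missing category for a present code is
    an error naming the code.
    """
    category_map = category_map if category_map is not None else default_category_map()
    periods = tuple(sorted(summaries, key=lambda p: _PERIOD_ORDER.get(p, 99)))
    nodes: list[FlowchartNode] = []
    edges: list[FlowchartEdge] = []
    for period in periods:
        summary = summaries[period]
        max_freq = max(summary.frequency.values(), default=0)
        max_dur = max(summary.mean_duration_s.values(), default=0.0)
        node_codes = set()
        for code in sorted(summary.frequency):
            freq = summary.frequency[code]
            if drop_zero_frequency and freq == 0:
                continue
            if code not in category_map:
                raise ValueError(f"behavior code {code!r} has no category in the map")
            category = category_map[code]
            nodes.append(
                FlowchartNode(
                    code=code,
                    period=period,
                    height=round(_scale(freq, max_freq), 6),
                    base=round(_scale(summary.mean_duration_s[code], max_dur), 6),
                    category=category,
                    color=_CATEGORY_COLORS[category],
                )
            )
            node_codes.add(code)
        sig = [d for d in dyads.get(period, ()) if d.significant]
        max_chi2 = max((d.chi2 for d in sig), default=0.0)
        for d in sorted(sig, key=lambda d: (d.pre_code, d.post_code)):
            if d.pre_code not in node_codes or d.post_code not in node_codes:
                raise ValueError(
                    f"dyad {d.pre_code}->{d.post_code} references a code "
                    f"absent from the {period} summary"
                )
            src_cat = category_map[d.pre_code]
            edges.append(
                FlowchartEdge(
                    pre_code=d.pre_code,
                    post_code=d.post_code,
                    period=period,
                    width=round(_scale(d.chi2, max_chi2), 6),
                    color=_CATEGORY_COLORS[src_cat],
                )
            )
    return FlowchartGraph(periods=periods, nodes=tuple(nodes), edges=tuple(edges))


# --- DOT ---------------------------------------------------------------

def _dot_node_id(period: str, code: str) -> str:
    return f"{period}__{code}".replace("/", "_")


def to_dot(graph: FlowchartGraph) -> str:
    """Canonical DOT text (clustered by period, deterministic ordering)."""
    lines = ["digraph flowchart {", "  rankdir=LR;"]
    for period in graph.periods:
        lines.append(f"  subgraph cluster_{_PERIOD_ORDER.get(period, 99)}_{period} {{")
        lines.append(f'    label="{period}";')
        for node in graph.nodes:
            if node.period != period:
                continue
            lines.append(
                f'    {_dot_node_id(period, node.code)} [label="{node.code}" '
                f'shape=box height={node.height} width={node.base} '
                f'style=filled fillcolor="{node.color}" category="{node.category}"];'
            )
        for edge in graph.edges:
            if edge.period != period:
                continue
            lines.append(
                f"    {_dot_node_id(period, edge.pre_code)} -> "
                f"{_dot_node_id(period, edge.post_code)} "
                f'[penwidth={edge.width} color="{edge.color}"];'
            )
        lines.append("  }")
    lines.append("}")
    return "\n".join(lines) + "\n"


_NODE_RE = re.compile(
    r'(\w+)\s+\[label="([^"]+)"\s+shape=box\s+height=([\d.]+)\s+width=([\d.]+)'
    r'\s+style=filled\s+fillcolor="([^"]+)"\s+category="([^"]+)"\];'
)
_EDGE_RE = re.compile(r'(\w+)\s+->\s+(\w+)\s+\[penwidth=([\d.]+)\s+color="([^"]+)"\];')
_CLUSTER_RE = re.compile(r"subgraph\s+cluster_\d+_(\w+)\s+\{")


def parse_dot(text: str) -> FlowchartGraph:
    """Parse the canonical DOT emitted by :func:`to_dot` back into a graph."""
    periods: list[str] = []
    nodes: list[FlowchartNode] = []
    edges: list[FlowchartEdge] = []
    current = None
    for line in text.splitlines():
        line = line.strip()
        m = _CLUSTER_RE.match(line)
        if m:
            current = m.group(1)
            periods.append(current)
            continue
        m = _NODE_RE.match(line)
        if m and current is not None:
            _, code, height, base, color, category = m.groups()
            nodes.append(
                FlowchartNode(
                    code=code, period=current, height=float(height),
                    base=float(base), category=category, color=color,
                )
            )
            continue
        m = _EDGE_RE.match(line)
        if m and current is not None:
            src, dst, width, color = m.groups()
            prefix = f"{current}__"
            edges.append(
                FlowchartEdge(
                    pre_code=src.removeprefix(prefix),
                    post_code=dst.removeprefix(prefix),
                    period=current, width=float(width), color=color,
                )
            )
    return FlowchartGraph(periods=tuple(periods), nodes=tuple(nodes), edges=tuple(edges))


# --- JSON --------------------------------------------------------------

def to_json(graph: FlowchartGraph) -> str:
    payload = {
        "periods": list(graph.periods),
        "nodes": [vars(n) for n in graph.nodes],
        "edges": [vars(e) for e in graph.edges],
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def flowchart_from_json(text: str) -> FlowchartGraph:
    payload = json.loads(text)
    return FlowchartGraph(
        periods=tuple(payload["periods"]),
        nodes=tuple(FlowchartNode(**n) for n in payload["nodes"]),
        edges=tuple(FlowchartEdge(**e) for e in payload["edges"]),
    )


def validate_flowchart_json(text: str) -> None:
    """Structural validation against the shipped flowchart schema.

    Raises ``ValueError`` naming the first violated constraint.
    """
    schema_path = Path(__file__).parent / "data" / "flowchart.schema.json"
    with open(schema_path, "r", encoding="utf-8") as fh:
        schema = json.load(fh)
    payload = json.loads(text)
    for key in schema["required"]:
        if key not in payload:
            raise ValueError(f"flowchart JSON lacks required key {key!r}")
    type_map = {"array": list, "object": dict, "string": str, "number": (int, float)}
    for key, spec in schema["properties"].items():
        if key in payload and not isinstance(payload[key], type_map[spec["type"]]):
            raise ValueError(f"flowchart JSON key {key!r} is not of type {spec['type']}")
    for collection, spec_key in (("nodes", "node"), ("edges", "edge")):
        item_schema = schema["definitions"][spec_key]
        for item in payload[collection]:
            for req in item_schema["required"]:
                if req not in item:
                    raise ValueError(f"{collection} entry lacks required key {req!r}")
            for key, fspec in item_schema["properties"].items():
                if key in item and not isinstance(item[key], type_map[fspec["type"]]):
                    raise ValueError(
                        f"{collection} entry key {key!r} is not of type {fspec['type']}"
                    )


# --- SVG ---------------------------------------------------------------

def to_svg(graph: FlowchartGraph) -> str:
    """Render the flowchart to SVG with matplotlib (rendering-only export)."""
    import io

    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    plt.rcParams["svg.hashsalt"] = "flowchart"  # deterministic element ids
    from matplotlib.patches import FancyArrowPatch, Rectangle

    n_cells = max(1, len(graph.periods))
    fig, axes = plt.subplots(1, n_cells, figsize=(4 * n_cells, 4), squeeze=False)
    for ax, period in zip(axes[0], graph.periods or ("",)):
        ax.set_title(period)
        ax.set_xticks([])
        ax.set_yticks([])
        cell_nodes = [n for n in graph.nodes if n.period == period]
        positions: dict[str, tuple[float, float]] = {}
        n_nodes = max(1, len(cell_nodes))
        for i, node in enumerate(cell_nodes):
            # nodes on a circle; geometry is qualitative, sizes carry the data
            angle = 2 * math.pi * i / n_nodes
            x, y = 5 + 3.5 * math.cos(angle), 5 + 3.5 * math.sin(angle)
            positions[node.code] = (x, y)
            ax.add_patch(
                Rectangle(
                    (x - node.base / 2, y - node.height / 2), node.base, node.height,
                    facecolor=node.color, edgecolor="black", linewidth=0.5,
                )
            )
            ax.annotate(node.code, (x, y), ha="center", va="center", fontsize=6)
        for edge in graph.edges:
            if edge.period != period:
                continue
            ax.add_patch(
                FancyArrowPatch(
                    positions[edge.pre_code], positions[edge.post_code],
                    arrowstyle="-|>", mutation_scale=8,
                    linewidth=edge.width, color=edge.color,
                    shrinkA=10, shrinkB=10,
                )
            )
        ax.set_xlim(0, 10)
        ax.set_ylim(0, 10)
    buffer = io.StringIO()
    fig.savefig(buffer, format="svg", metadata={"Date": None})
    plt.close(fig)
    return buffer.getvalue()


def export_flowchart(graph: FlowchartGraph, path: str | Path, format: str) -> Path:
    """Write the flowchart as DOT, JSON, or SVG."""
    path = Path(path)
    writers = {"DOT": to_dot, "JSON": to_json, "SVG": to_svg}
    fmt = format.upper()
    if fmt not in writers:
        raise ValueError(f"unknown flowchart format {format!r}; use DOT, JSON, or SVG")
    path.write_text(writers[fmt](graph), encoding="utf-8")
    return path
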