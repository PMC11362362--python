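"""Readers and writers: association CSVs, network files, session logs.

Two association-CSV dialects are supported. The aggregated dialect has one
(cue, response, count) row per directed pair. The raw dialect mirrors
free-association norming exports in which each row is one participant's
cue plus up to three responses (columns R1, R2, R3); rows are expanded to
one record per used response column, with sentinel strings ("no more
responses" etc.) dropped and identical (cue, response) pairs summed.

Networks are stored as a two-column tab-separated edge list (endpoints
lexicographically ordered, lines sorted) with a JSON metadata sidecar;
sessions as append-only JSON Lines, one event per line.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path

import networkx as nx

from .network import AssociationRecord, SemanticNetwork, normalize_token
from .recommend import Direction, Fallback, Recommendation, RecommendationRequest
from .ideaspace import IdeaSpace
from .session import Phase, ResponseEvent, SessionLog, Trial, trial_table

__all__ = [
    "DEFAULT_SENTINELS",
    "read_associations",
    "write_associations",
    "write_network",
    "read_network",
    "write_session_logs",
    "read_session_logs",
    "write_trial_table",
]

#: Missing-response markers dropped by the raw-dialect reader. The exact
#: strings vary across dataset releases, so they are configuration, not
#: a hard-coded constant.
DEFAULT_SENTINELS = frozenset(
    {"", "no more responses", "unknown word", "missing", "na", "n/a"}
)


def read_associations(
    path,
    dialect: str = "aggregated",
    responses_used: str = "R123",
    sentinels=DEFAULT_SENTINELS,
) -> list[AssociationRecord]:
    """Read association records from a CSV file.

    ``dialect="aggregated"`` expects columns cue,response,count;
    ``dialect="raw_swow"`` expects participant,cue,R1,R2,R3 and expands
    each row into one record per used response column
    (``responses_used="R1"`` or ``"R123"``), dropping sentinels and
    summing repeated (cue, response) pairs.
    """
    if dialect not in ("aggregated", "raw_swow"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    if responses_used not in ("R1", "R123"):
        raise ValueError(f"responses_used must be 'R1' or 'R123', got {responses_used!r}")
    sentinels = {normalize_token(s) for s in sentinels}

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError("no associations")
        header = [h.strip() for h in reader.fieldnames]
        if dialect == "aggregated":
            required = ["cue", "response", "count"]
        else:
            required = ["participant", "cue", "R1", "R2", "R3"]
        missing = [c for c in required if c not in header]
        if missing:
            raise ValueError(f"header missing columns {missing} for dialect {dialect!r}")

        records: list[AssociationRecord] = []
        counts: dict[tuple[str, str], int] = {}
        for lineno, row in enumerate(reader, start=2):
            try:
                if dialect == "aggregated":
                    cue = normalize_token(row["cue"])
                    resp = normalize_token(row["response"])
                    count = int(row["count"])
                    records.append(AssociationRecord(cue, resp, count))
                else:
                    cue = normalize_token(row["cue"])
                    if not cue:
                        raise ValueError("empty cue")
                    cols = ["R1"] if responses_used == "R1" else ["R1", "R2", "R3"]
                    for col in cols:
                        resp = normalize_token(row[col] or "")
                        if resp in sentinels:
                            continue
                        counts[(cue, resp)] = counts.get((cue, resp), 0) + 1
            except (KeyError, TypeError, ValueError) as err:
                raise ValueError(f"malformed row at line {lineno}: {err}") from err

    if dialect == "raw_swow":
        records = [
            AssociationRecord(cue, resp, n)
            for (cue, resp), n in sorted(counts.items())
        ]
    if not records:
        raise ValueError("no associations")
    return records


def write_associations(records: list[AssociationRecord], path) -> None:
    """Write records in the aggregated dialect (cue,response,count)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
        writer.writerow(["cue", "response", "count"])
        for rec in records:
            writer.writerow([rec.cue, rec.response, rec.count])


def _sidecar_path(edge_path) -> Path:
    return Path(str(edge_path) + ".meta.json")


def write_network(net: SemanticNetwork, edge_path, meta_path=None) -> None:
    """Write the edge-list TSV and its JSON metadata sidecar."""
    meta_path = meta_path if meta_path is not None else _sidecar_path(edge_path)
    lines = sorted(tuple(sorted(e)) for e in net.graph.edges)
    with open(edge_path, "w", encoding="utf-8") as fh:
        for a, b in lines:
            fh.write(f"{a}\t{b}\n")
    meta = {
        "min_count": net.metadata.get("min_count"),
        "count_mode": net.metadata.get("count_mode"),
        "lcc": net.metadata.get("lcc"),
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "nodes": sorted(net.graph.nodes),
    }
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_network(edge_path, meta_path=None) -> SemanticNetwork:
    """Read an edge-list TSV plus sidecar, validating node and edge counts."""
    meta_path = meta_path if meta_path is not None else _sidecar_path(edge_path)
    with open(meta_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    known = set(meta.get("nodes", []))

    graph = nx.Graph()
    graph.add_nodes_from(known)
    with open(edge_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"malformed edge at line {lineno}: {line!r}")
            a, b = parts
            if known and (a not in known or b not in known):
                raise ValueError(
                    f"edge at line {lineno} references unknown node: {line!r}"
                )
            graph.add_edge(a, b)

    if meta.get("n_edges") is not None and graph.number_of_edges() != meta["n_edges"]:
        raise ValueError(
            f"edge count mismatch: sidecar says {meta['n_edges']}, "
            f"file has {graph.number_of_edges()}"
        )
    if meta.get("n_nodes") is not None and graph.number_of_nodes() != meta["n_nodes"]:
        raise ValueError(
            f"node count mismatch: sidecar says {meta['n_nodes']}, "
            f"file has {graph.number_of_nodes()}"
        )
    metadata = {
        "min_count": meta.get("min_count"),
        "count_mode": meta.get("count_mode"),
        "lcc": meta.get("lcc"),
    }
    net = SemanticNetwork(graph, metadata)
    if metadata["lcc"] and not net.is_connected():
        warnings.warn("sidecar flags LCC but the stored graph is not connected")
    return net


# --- session logs (JSON Lines, one event object per line) -----------------


def _session_events(session: SessionLog):
    yield {
        "event": "session_start",
        "participant_id": session.participant_id,
        "seed": session.seed,
        "config": session.config,
    }
    for trial in session.trials:
        yield {
            "event": "trial_start",
            "trial_id": trial.trial_id,
            "object": trial.object,
            "distance": trial.distance,
            "direction": Direction(trial.direction).value,
        }
        for r in trial.responses_in_phase(Phase.PRE):
            yield _response_event(r)
        if trial.impasse_time is not None:
            yield {
                "event": "impasse",
                "trial_id": trial.trial_id,
                "t": trial.impasse_time,
            }
        if trial.recommendation is not None:
            rec = trial.recommendation
            yield {
                "event": "recommendation",
                "trial_id": trial.trial_id,
                "word": rec.word,
                "avg_distance_to_idea_space": rec.avg_distance_to_idea_space,
                "rank": rec.rank,
                "fallback_used": Fallback(rec.fallback_used).value,
                "distance_used": rec.distance_used,
                "t": trial.rec_shown_time,
            }
        for r in trial.responses_in_phase(Phase.POST):
            yield _response_event(r)
        yield {"event": "trial_end", "trial_id": trial.trial_id}
    yield {"event": "session_end", "participant_id": session.participant_id}


def _response_event(r: ResponseEvent) -> dict:
    out = {
        "event": "response",
        "trial_id": r.trial_id,
        "phase": Phase(r.phase).value,
        "text": r.text,
        "t_start": r.t_start,
        "t_typing": r.t_typing,
    }
    if r.originality is not None:
        out["originality"] = r.originality
    return out


def write_session_logs(sessions: list[SessionLog], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for session in sessions:
            for event in _session_events(session):
                fh.write(json.dumps(event, sort_keys=True) + "\n")


def read_session_logs(path) -> list[SessionLog]:
    """Rebuild sessions from a JSON Lines event log.

    Unknown event kinds (e.g. reserved keystroke events) are ignored, so
    logs remain forward-compatible with richer recorders.
    """
    sessions: list[SessionLog] = []
    session: SessionLog | None = None
    trials: dict[str, Trial] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                ev = json.loads(line)
            except json.JSONDecodeError as err:
                raise ValueError(f"malformed log line {lineno}: {err}") from err
            kind = ev.get("event")
            if kind == "session_start":
                session = SessionLog(
                    participant_id=ev["participant_id"],
                    seed=ev["seed"],
                    config=ev.get("config", {}),
                )
                sessions.append(session)
                trials = {}
            elif session is None:
                raise ValueError(f"event before session_start at line {lineno}")
            elif kind == "trial_start":
                trial = Trial(
                    trial_id=ev["trial_id"],
                    object=ev["object"],
                    distance=ev["distance"],
                    direction=Direction(ev["direction"]),
                )
                trials[trial.trial_id] = trial
                session.trials.append(trial)
            elif kind == "response":
                trials[ev["trial_id"]].responses.append(
                    ResponseEvent(
                        trial_id=ev["trial_id"],
                        text=ev["text"],
                        phase=Phase(ev["phase"]),
                        t_start=ev["t_start"],
                        t_typing=ev["t_typing"],
                        originality=ev.get("originality"),
                    )
                )
            elif kind == "impasse":
                trials[ev["trial_id"]].impasse_time = ev["t"]
            elif kind == "recommendation":
                trial = trials[ev["trial_id"]]
                request = RecommendationRequest(
                    object=trial.object,
                    distance=trial.distance,
                    direction=trial.direction,
                    idea_space=IdeaSpace(),
                )
                trial.recommendation = Recommendation(
                    word=ev["word"],
                    request=request,
                    avg_distance_to_idea_space=ev.get("avg_distance_to_idea_space"),
                    rank=ev.get("rank", 0),
                    fallback_used=Fallback(ev.get("fallback_used", "none")),
                    distance_used=ev.get("distance_used", trial.distance),
                )
                trial.rec_shown_time = ev.get("t")
            # other kinds (keystroke, session_end, trial_end): no state
    return sessions


def write_trial_table(
    sessions: list[SessionLog],
    path,
    net: SemanticNetwork | None = None,
    stoplist: set[str] | None = None,
) -> None:
    """Concatenate per-session trial tables into one CSV."""
    import pandas as pd

    tables = [trial_table(s, net=net, stoplist=stoplist) for s in sessions]
    df = pd.concat(tables, ignore_index=True) if tables else None
    if df is None:
        raise ValueError("no sessions to score")
    df.to_csv(path, index=False)
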