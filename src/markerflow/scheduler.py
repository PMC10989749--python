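"""Deterministic dynamic task scheduling.

A TaskGraph holds named tasks with declared dependencies; ``schedule``
dispatches ready tasks to a bounded worker pool as workers free up.
Because every task writes only its own outputs and consumers run only
after their inputs completed, results are independent of thread count
and of interleaving. A failed task cancels its dependents (only) and
the failure is recorded, not raised, so sibling work continues.
"""

from __future__ import annotations

import threading
import time
from concurrent.futures import FIRST_COMPLETED, ThreadPoolExecutor, wait
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Any, Callable

__all__ = ["Task", "TaskGraph", "schedule"]


@dataclass
class Task:
    name: str
    fn: Callable[[], Any]
    deps: tuple[str, ...] = ()


@dataclass
class CompletionRecord:
    name: str
    status: str  # ok | failed | cancelled
    error: str | None = None
    started: float = 0.0
    finished: float = 0.0


@dataclass
class TaskGraph:
    tasks: dict[str, Task] = field(default_factory=dict)
    results: dict[str, Any] = field(default_factory=dict)

    def add(self, name: str, fn: Callable[[], Any], deps: tuple[str, ...] | list[str] = ()) -> None:
        if name in self.tasks:
            raise ValueError(f"duplicate task {name!r}")
        self.tasks[name] = Task(name, fn, tuple(deps))

    def run(self, threads: int = 1) -> list[CompletionRecord]:
        return schedule(self, threads)


def schedule(graph: TaskGraph, threads: int = 1) -> list[CompletionRecord]:
    """Run the graph with at most ``threads`` tasks in flight.

    Returns the completion log in finish order. Raises on a dependency
    cycle or an unknown dependency; task errors are captured in the log.
    """
    if threads < 1:
        raise ValueError("threads must be >= 1")
    for task in graph.tasks.values():
        for dep in task.deps:
            if dep not in graph.tasks:
                raise ValueError(f"task {task.name!r} depends on unknown task {dep!r}")
    sorter = TopologicalSorter({n: t.deps for n, t in graph.tasks.items()})
    try:
        sorter.prepare()
    except CycleError as exc:
        raise ValueError(f"task graph has a cycle: {exc.args[1]}") from exc

    log: list[CompletionRecord] = []
    failed: set[str] = set()
    lock = threading.Lock()

    def run_one(name: str) -> CompletionRecord:
        rec = CompletionRecord(name, "ok", started=time.monotonic())
        try:
            out = graph.tasks[name].fn()
            with lock:
                graph.results[name] = out
        except Exception as exc:  # noqa: BLE001 - captured into the log
            rec.status = "failed"
            rec.error = f"{type(exc).__name__}: {exc}"
        rec.finished = time.monotonic()
        return rec

    with ThreadPoolExecutor(max_workers=threads) as pool:
        futures = {}
        while sorter.is_active() or futures:
            for name in sorter.get_ready():
                if any(dep in failed for dep in _ancestry(graph, name, failed)):
                    rec = CompletionRecord(name, "cancelled",
                                           error="upstream failure")
                    failed.add(name)
                    log.append(rec)
                    sorter.done(name)
                    continue
                futures[pool.submit(run_one, name)] = name
            if not futures:
                continue
            done, _ = wait(futures, return_when=FIRST_COMPLETED)
            for fut in done:
                name = futures.pop(fut)
                rec = fut.result()
                if rec.status == "failed":
                    failed.add(name)
                log.append(rec)
                sorter.done(name)
    return log


def _ancestry(graph: TaskGraph, name: str, failed: set[str]) -> set[str]:
    """Direct dependencies; transitive failures propagate because each
    cancelled task is itself added to ``failed``."""
    return set(graph.tasks[name].deps)
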