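"""Serial and coordinator/worker execution of the per-interval analysis.

The coordinator dispatches one interval per idle worker with a COMPUTE
message; a worker answers with DONE (carrying the temp-file path) and is
immediately given the next unprocessed interval; when none remain every
worker receives FINISH. Temporary per-interval tables are merged in plan
order, so the final file is byte-identical to a serial run regardless of
worker count or completion order.

Two transports implement the same protocol: an in-process backend (used by
tests, optionally with a randomized completion order) and a
multiprocessing backend with one OS process per worker.
"""

from __future__ import annotations

import logging
import multiprocessing as mp
import os
import random
import tempfile
from collections import deque
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

from .alignment_io import (
    AlignmentHandle,
    GenomicInterval,
    open_alignment,
    reference_window,
)
from .editing_caller import (
    CallerConfig,
    EditingSiteRecord,
    call_site,
    merge_outputs,
    temp_table_name,
    write_table,
)
from .errors import WorkerFailureError
from .pileup_engine import PileupConfig, TraversalStats, traverse

logger = logging.getLogger("redikit")

COMPUTE = "COMPUTE"
DONE = "DONE"
FINISH = "FINISH"


@dataclass(frozen=True)
class WorkMessage:
    kind: str  # COMPUTE | DONE | FINISH
    interval: Optional[GenomicInterval] = None
    worker_id: Optional[int] = None
    temp_path: Optional[str] = None


@dataclass
class RunConfig:
    pileup: PileupConfig = field(default_factory=PileupConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    scratch: Optional[str] = None
    workers: int = 1

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ValueError("worker count must be >= 1")


@dataclass
class RunResult:
    output: str
    trace: List[Tuple[int, str, Optional[GenomicInterval]]]
    records: int
    stats: Optional[TraversalStats] = None


def process_interval(
    handle: AlignmentHandle,
    fasta: str,
    interval: GenomicInterval,
    config: RunConfig,
    stats: Optional[TraversalStats] = None,
) -> List[EditingSiteRecord]:
    """Traverse one interval and call candidate sites against the reference."""
    ref = reference_window(fasta, interval).bases
    records: List[EditingSiteRecord] = []
    for pileup in traverse(handle, interval, config.pileup, stats=stats):
        rec = call_site(pileup, ref[pileup.pos - interval.start], config.caller)
        if rec is not None:
            records.append(rec)
    return records


def whole_genome_intervals(handle: AlignmentHandle) -> List[GenomicInterval]:
    return [GenomicInterval(c, 0, ln) for c, ln in handle.chromosomes]


def run_serial(
    bam: Union[str, os.PathLike],
    fasta: Union[str, os.PathLike],
    intervals: Optional[Sequence[GenomicInterval]],
    config: RunConfig,
    out_path: Union[str, os.PathLike],
    collect_stats: bool = False,
) -> RunResult:
    """Process intervals in order into a single output table."""
    bam, fasta, out_path = str(bam), str(fasta), str(out_path)
    stats = TraversalStats() if collect_stats else None
    with open_alignment(bam) as handle:
        if intervals is None:
            intervals = whole_genome_intervals(handle)
        records: List[EditingSiteRecord] = []
        for interval in intervals:
            recs = process_interval(handle, fasta, interval, config, stats=stats)
            logger.info("interval %s records=%d", interval, len(recs))
            records.extend(recs)
    count = write_table(records, out_path, config.pileup.min_base_quality)
    return RunResult(output=out_path, trace=[], records=count, stats=stats)


def _worker_process_interval(
    bam: str, fasta: str, interval: GenomicInterval, config: RunConfig, scratch: str
) -> str:
    with open_alignment(bam) as handle:
        records = process_interval(handle, fasta, interval, config)
    path = os.path.join(scratch, temp_table_name(interval))
    write_table(records, path, config.pileup.min_base_quality)
    return path


def _mp_worker(bam, fasta, config, scratch, worker_id, conn, done_queue):
    """Worker loop for the multiprocessing backend."""
    while True:
        msg: WorkMessage = conn.recv()
        if msg.kind == FINISH:
            return
        try:
            path = _worker_process_interval(bam, fasta, msg.interval, config, scratch)
        except Exception as exc:  # surfaced by the coordinator
            done_queue.put(("ERROR", worker_id, msg.interval, repr(exc)))
            return
        done_queue.put((DONE, worker_id, msg.interval, path))


def run_parallel(
    bam: Union[str, os.PathLike],
    fasta: Union[str, os.PathLike],
    intervals: Optional[Sequence[GenomicInterval]],
    config: RunConfig,
    out_path: Union[str, os.PathLike],
    backend: str = "local",
    rng: Optional[random.Random] = None,
) -> RunResult:
    """Coordinator/worker execution; output byte-identical to run_serial.

    ``backend='local'`` simulates the protocol in-process (``rng``
    randomizes which in-flight interval completes first); ``'process'``
    spawns one OS process per worker.
    """
    bam, fasta, out_path = str(bam), str(fasta), str(out_path)
    if intervals is None:
        with open_alignment(bam) as handle:
            intervals = whole_genome_intervals(handle)
    intervals = list(intervals)
    scratch = config.scratch or tempfile.mkdtemp(prefix="redikit_")
    os.makedirs(scratch, exist_ok=True)

    if backend == "local":
        trace, temp_paths = _run_local(bam, fasta, intervals, config, scratch, rng)
    elif backend == "process":
        trace, temp_paths = _run_process(bam, fasta, intervals, config, scratch)
    else:
        raise ValueError(f"unknown backend {backend!r}")

    ordered = [temp_paths[iv] for iv in intervals]
    count = merge_outputs(
        ordered, out_path, config.pileup.min_base_quality, delete=True
    )
    return RunResult(output=out_path, trace=trace, records=count)


def _run_local(bam, fasta, intervals, config, scratch, rng):
    trace: List[Tuple[int, str, Optional[GenomicInterval]]] = []
    temp_paths = {}
    pending = deque(intervals)
    idle = deque(range(config.workers))
    inflight: List[Tuple[int, GenomicInterval]] = []
    with open_alignment(bam) as handle:
        while pending or inflight:
            while pending and idle:
                worker = idle.popleft()
                interval = pending.popleft()
                trace.append((worker, COMPUTE, interval))
                inflight.append((worker, interval))
            pick = rng.randrange(len(inflight)) if rng is not None else 0
            worker, interval = inflight.pop(pick)
            records = process_interval(handle, fasta, interval, config)
            path = os.path.join(scratch, temp_table_name(interval))
            write_table(records, path, config.pileup.min_base_quality)
            logger.info("interval %s records=%d", interval, len(records))
            temp_paths[interval] = path
            trace.append((worker, DONE, interval))
            idle.append(worker)
    for worker in range(config.workers):
        trace.append((worker, FINISH, None))
    return trace, temp_paths


def _run_process(bam, fasta, intervals, config, scratch):
    ctx = mp.get_context("fork" if "fork" in mp.get_all_start_methods() else "spawn")
    done_queue = ctx.Queue()
    conns = []
    procs = []
    for worker in range(config.workers):
        parent, child = ctx.Pipe()
        proc = ctx.Process(
            target=_mp_worker,
            args=(bam, fasta, config, scratch, worker, child, done_queue),
        )
        proc.start()
        conns.append(parent)
        procs.append(proc)

    trace: List[Tuple[int, str, Optional[GenomicInterval]]] = []
    temp_paths = {}
    pending = deque(intervals)
    finished = [False] * config.workers
    inflight = 0
    try:
        for worker in range(config.workers):
            if pending:
                interval = pending.popleft()
                conns[worker].send(WorkMessage(COMPUTE, interval=interval))
                trace.append((worker, COMPUTE, interval))
                inflight += 1
            else:
                conns[worker].send(WorkMessage(FINISH))
                trace.append((worker, FINISH, None))
                finished[worker] = True
        while inflight:
            kind, worker, interval, payload = done_queue.get()
            if kind == "ERROR":
                raise WorkerFailureError(
                    f"worker {worker} failed on {interval}: {payload}"
                )
            trace.append((worker, DONE, interval))
            temp_paths[interval] = payload
            inflight -= 1
            if pending:
                nxt = pending.popleft()
                conns[worker].send(WorkMessage(COMPUTE, interval=nxt))
                trace.append((worker, COMPUTE, nxt))
                inflight += 1
            else:
                conns[worker].send(WorkMessage(FINISH))
                trace.append((worker, FINISH, None))
                finished[worker] = True
    finally:
        for worker, proc in enumerate(procs):
            if not finished[worker] and proc.is_alive():
                proc.terminate()
            proc.join()
        for conn in conns:
            conn.close()
    return trace, temp_paths


def schedule_trace(result: RunResult) -> List[Tuple[int, str, Optional[GenomicInterval]]]:
    """Per-worker assignment log: (worker id, message kind, interval)."""
    return result.trace
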