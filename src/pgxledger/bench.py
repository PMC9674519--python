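"""Workload harness: throughput, latency and success rate on the simulated
clock, plus a linear-ramp scalability probe.

Transactions are injected at a configured send rate (tx per tick) and the
sealer drains the pool each tick under a capacity budget; Write operations
cost more budget than Reads, which reproduces the qualitative asymmetry of
writing to a blockchain versus querying it. All metrics are computed from
the raw receipt log — submission tick, sealing tick, status — and are fully
deterministic given (config, seed). They are simulation metrics: no
wall-clock figure from any deployed network is a target here.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import vocab
from .errors import PgxLedgerError
from .ledger import build_transaction
from .synth import Scenario


class SetupRequired(PgxLedgerError):
    """Benchmark invoked without an initialised scenario."""


@dataclass(frozen=True)
class WorkloadConfig:
    operation_class: str  # "Write" | "Read"
    tx_total: int = 200
    send_rate: int = 10  # transactions injected per tick
    rounds: int = 1
    workers: int = 1  # recorded for provenance; execution is single-sealer
    seed: int = 0
    seal_capacity: int = 10  # sealing budget per tick, in cost units
    write_cost: int = 2  # budget units per Write op (Reads cost 1)
    authorized: bool = True

    def __post_init__(self) -> None:
        if self.operation_class not in ("Write", "Read"):
            raise ValueError("operation_class must be 'Write' or 'Read'")
        for name in ("tx_total", "send_rate", "rounds", "workers",
                     "seal_capacity", "write_cost"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class RoundMetrics:
    round: int
    tx_count: int
    succeeded: int
    throughput: float
    latency_avg: float


@dataclass
class BenchmarkResult:
    config: WorkloadConfig
    throughput: float  # succeeded tx per tick
    latency_min: float
    latency_avg: float
    latency_max: float
    success_rate: float
    elapsed_ticks: int
    receipt_log: list[dict] = field(default_factory=list)
    per_round: list[RoundMetrics] = field(default_factory=list)

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.receipt_log)

    def summary(self) -> dict:
        return {
            "operation_class": self.config.operation_class,
            "tx_total": self.config.tx_total,
            "send_rate": self.config.send_rate,
            "throughput": self.throughput,
            "latency_min": self.latency_min,
            "latency_avg": self.latency_avg,
            "latency_max": self.latency_max,
            "success_rate": self.success_rate,
            "elapsed_ticks": self.elapsed_ticks,
        }


def recompute_metrics(receipt_log: list[dict]) -> dict:
    """Recompute every aggregate from the raw receipt log alone; the oracle
    against which reported metrics are checked."""
    if not receipt_log:
        return {"throughput": 0.0, "latency_min": 0.0, "latency_avg": 0.0,
                "latency_max": 0.0, "success_rate": 0.0, "elapsed_ticks": 0}
    latencies = [row["seal_tick"] - row["submit_tick"] for row in receipt_log]
    succeeded = sum(1 for row in receipt_log if row["status"] == "succeeded")
    elapsed = max(r["seal_tick"] for r in receipt_log) \
        - min(r["submit_tick"] for r in receipt_log) + 1
    return {
        "throughput": succeeded / elapsed,
        "latency_min": float(min(latencies)),
        "latency_avg": float(sum(latencies) / len(latencies)),
        "latency_max": float(max(latencies)),
        "success_rate": succeeded / len(receipt_log),
        "elapsed_ticks": elapsed,
    }


# --- operation generators -------------------------------------------------


def _write_ops(scenario: Scenario, config: WorkloadConfig, rng: np.random.Generator):
    """Authorized Writes alternate permission grants with fresh metadata
    publications; unauthorized Writes are ticket requests that the policy
    denies."""
    net = scenario.network
    cube = vocab.all_triples()
    for i in range(config.tx_total):
        if not config.authorized:
            requester = scenario.requesters[i % len(scenario.requesters)]
            patient = scenario.patients[int(rng.integers(len(scenario.patients)))]
            yield requester, "ACMSC", "requestAccessTicket", {
                "patient": patient.address,
                "drug": str(rng.choice(vocab.drugs())),
                "purpose": str(rng.choice(vocab.purposes())),
            }, "requestAccessTicket"
        elif i % 2 == 0:
            patient = scenario.patients[(i // 2) % len(scenario.patients)]
            d, r, p = cube[int(rng.integers(len(cube)))]
            yield patient, "ACMSC", "setAccessPermission", {
                "triples": [{"drug": d, "role": r, "purpose": p}],
            }, "setAccessPermission"
        else:
            patient = scenario.patients[(i // 2) % len(scenario.patients)]
            profile = scenario.profiles[(i // 2) % len(scenario.patients)]
            from .synth import make_pgx_record  # local import avoids cycle at module load

            # block height namespaces ids so successive workloads on one
            # scenario never collide
            record, recommendations = make_pgx_record(
                profile, patient.address,
                f"bench-{len(net.node.blocks)}-{config.seed}-{i}", rng,
                created_at=net.node.now)
            pointer, digest = net.store.store_record(scenario.creator.address, record)
            yield scenario.creator, "DSC", "createData", {"metadata": {
                "record_id": record["record_id"], "patient": patient.address,
                "creator": scenario.creator.address,
                "recommendations": recommendations,
                "data_hash": digest, "pointer": pointer,
            }}, "createData"


def _read_ops(scenario: Scenario, config: WorkloadConfig, rng: np.random.Generator):
    for i in range(config.tx_total):
        patient = scenario.patients[int(rng.integers(len(scenario.patients)))]
        if i % 2 == 0:
            yield scenario.requesters[i % len(scenario.requesters)], \
                "DSC", "getMetadata", {"patient": patient.address}, "getMetadata"
        else:
            d, r, p = vocab.all_triples()[int(rng.integers(54))]
            yield scenario.requesters[i % len(scenario.requesters)], \
                "ACMSC", "evaluatePolicy", {
                    "patient": patient.address, "drug": d, "role": r, "purpose": p,
                }, "evaluatePolicy"


# --- the harness ----------------------------------------------------------


def run_workload(scenario: Scenario, config: WorkloadConfig) -> BenchmarkResult:
    """Inject ``tx_total`` operations at ``send_rate`` per tick, sealing
    each tick under the capacity budget, and measure from the receipts."""
    if scenario is None or not scenario.patients:
        raise SetupRequired("build_scenario must run first")
    net = scenario.network
    node = net.node
    rng = np.random.default_rng(config.seed)
    gen = _write_ops if config.operation_class == "Write" else _read_ops
    ops = list(gen(scenario, config, rng))
    cost = config.write_cost if config.operation_class == "Write" else 1

    submit_tick: dict[str, int] = {}
    op_name: dict[str, str] = {}
    start_tick = node.now
    receipt_rows: list[dict] = []
    i = 0
    while i < len(ops) or node.pending:
        rel = node.now - start_tick
        while i < len(ops) and i // config.send_rate <= rel:
            wallet, contract, function, args, name = ops[i]
            tx = build_transaction(wallet.keypair, contract, function, args,
                                   node.next_nonce(wallet.address))
            node.submit_transaction(tx)
            submit_tick[tx.tx_id] = node.now
            op_name[tx.tx_id] = name
            i += 1
        block = node.seal_block(max_txs=max(1, config.seal_capacity // cost),
                                advance=0)
        for tx, receipt in zip(block.transactions, block.receipts):
            receipt_rows.append({
                "tx_id": tx.tx_id, "function": op_name[tx.tx_id],
                "operation_class": config.operation_class,
                "submit_tick": submit_tick[tx.tx_id], "seal_tick": block.timestamp,
                "status": receipt.status, "reason": receipt.reason,
            })
        node.advance_clock(1)

    metrics = recompute_metrics(receipt_rows)
    per_round = []
    chunk = max(1, len(receipt_rows) // config.rounds)
    for r in range(config.rounds):
        rows = receipt_rows[r * chunk:(r + 1) * chunk] if r < config.rounds - 1 \
            else receipt_rows[r * chunk:]
        if not rows:
            continue
        m = recompute_metrics(rows)
        per_round.append(RoundMetrics(round=r, tx_count=len(rows),
                                      succeeded=sum(1 for x in rows
                                                    if x["status"] == "succeeded"),
                                      throughput=m["throughput"],
                                      latency_avg=m["latency_avg"]))
    return BenchmarkResult(config=config, receipt_log=receipt_rows,
                           per_round=per_round, **metrics)


@dataclass
class RampResult:
    rates: list[int]
    results: list[BenchmarkResult]
    latency_threshold: float
    knee_rate: int | None  # first rate whose avg latency exceeds the threshold

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([res.summary() for res in self.results])


def run_scalability_ramp(scenario: Scenario, *, start_rate: int = 2, step: int = 2,
                         n_steps: int = 5, tx_per_step: int = 60, seed: int = 0,
                         latency_threshold: float = 2.0,
                         operation_class: str = "Write",
                         seal_capacity: int = 10, write_cost: int = 2) -> RampResult:
    """Run successive workloads at linearly increasing send rates and report
    the knee where average latency first exceeds the threshold."""
    rates, results, knee = [], [], None
    for k in range(n_steps):
        rate = start_rate + k * step
        res = run_workload(scenario, WorkloadConfig(
            operation_class=operation_class, tx_total=tx_per_step, send_rate=rate,
            seed=seed + k, seal_capacity=seal_capacity, write_cost=write_cost))
        rates.append(rate)
        results.append(res)
        if knee is None and res.latency_avg > latency_threshold:
            knee = rate
    return RampResult(rates=rates, results=results,
                      latency_threshold=latency_threshold, knee_rate=knee)
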