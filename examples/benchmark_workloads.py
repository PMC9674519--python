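"""Throughput/latency measurement on the simulated clock.

Runs a Write and a Read workload against an initialised scenario, then a
linear send-rate ramp. Throughput is succeeded transactions per tick and
latency is ticks from submission to sealing; once the send rate exceeds
sealer capacity the backlog grows and the latency knee appears. All numbers
are deterministic functions of (config, seed).
"""

from pgxledger import WorkloadConfig, build_scenario, run_scalability_ramp, run_workload

scenario = build_scenario(n_patients=5, n_requesters=3, policy_density=0.5,
                          seed=41, config={"allow_multiple_records_per_pair": True})

for op_class in ("Write", "Read"):
    result = run_workload(scenario, WorkloadConfig(
        operation_class=op_class, tx_total=120, send_rate=8, seal_capacity=10))
    print(f"{op_class:5s}: throughput {result.throughput:5.2f} tx/tick | "
          f"latency avg {result.latency_avg:4.2f} ticks "
          f"(min {result.latency_min:.0f}, max {result.latency_max:.0f}) | "
          f"success {result.success_rate:.2f}")

ramp = run_scalability_ramp(scenario, start_rate=2, step=2, n_steps=5,
                            tx_per_step=60, seal_capacity=10, write_cost=2)
print("\nscalability ramp (Write):")
print(ramp.frame()[["send_rate", "throughput", "latency_avg"]].to_string(index=False))
print(f"latency knee at send rate {ramp.knee_rate} "
      f"(capacity is {10 // 2} writes/tick)")
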