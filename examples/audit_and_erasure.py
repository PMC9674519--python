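"""The immutable audit trail and the right to erasure.

A patient lists every event concerning their address; the off-chain record
is then erased. Afterwards no request can release data (the on-chain
pointer dangles), yet the chain still verifies and replays — deletion of
personal data coexists with an immutable, non-identifying audit history.
"""

from pgxledger import Network, replay, verify_chain
from pgxledger.synth import make_pgx_record, sample_patients

net = Network(seed=31)
patient = net.onboard_patient()
pharmacist = net.onboard_requester("pharmacist")
lab = net.onboard_creator()
profile = sample_patients(1, net.rng)[0]
record, recs = make_pgx_record(profile, patient.address, "rec-1", net.rng)
net.publish_record(lab, record, recs)
net.grant(patient, [("codeine", "pharmacist", "treatment")])
net.request_flow(pharmacist, patient.address, "codeine", "treatment")

print("events concerning the patient, in chain order:")
for ev in net.node.get_events(address=patient.address):
    print(f"  block {ev.block_index:3d}  {ev.contract:5s}  {ev.name}")

removed = net.store.erase_patient(lab.address, patient.address)
print(f"\nerased {removed} off-chain record(s)")
flow = net.request_flow(pharmacist, patient.address, "codeine", "treatment")
print("release attempt after erasure:", flow.failure_reason)  # POINTER_DANGLING
ok, _ = verify_chain(net.node.blocks)
print("chain still verifies:", ok)
print("replay still matches live state:", replay(net.node.blocks) == net.node.state)
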