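"""The complete release workflow, from registration to one-time delivery.

Builds a minimal network (one patient, one pharmacist, one genomic lab),
publishes a record, grants a single consent triple and runs the thirteen
workflow steps. The printed transcript shows each stage succeeding and the
delivered document matching the stored record byte for byte.
"""

from pgxledger import Network
from pgxledger.synth import make_pgx_record, sample_patients

net = Network(seed=11)
patient = net.onboard_patient()
pharmacist = net.onboard_requester("pharmacist")
lab = net.onboard_creator()

profile = sample_patients(1, net.rng)[0]
record, recommendations = make_pgx_record(profile, patient.address, "rec-1", net.rng)
net.publish_record(lab, record, recommendations)
print(f"patient CYP2D6 class: {profile.cyp2d6}")
print(f"codeine recommendation: "
      f"{next(r['recommendation'] for r in recommendations if r['drug'] == 'codeine')}")

net.grant(patient, [("codeine", "pharmacist", "treatment")])
flow = net.request_flow(pharmacist, patient.address, "codeine", "treatment")

for step in flow.steps:
    print(f"[step {step.step:2d}] {'ok ' if step.ok else 'FAIL'} {step.description}")
print("delivered document equals stored record:", flow.document == record)
# A second dereference of the same capability URL would raise UrlExhausted:
# delivery is strictly one-time.
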