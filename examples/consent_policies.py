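"""Consent as a decision tree over (drug, role, purpose) triples.

Compiles a small allow-set, prints its Boolean form, and shows that
evaluation is exact set membership: revoking a triple takes effect for the
very next request, and an empty policy denies everything.
"""

from pgxledger import Network, boolean_formula, compile_tree, evaluate_tree

triples = [("codeine", "pharmacist", "treatment"),
           ("codeine", "physician", "treatment"),
           ("abacavir", "physician", "research")]
tree = compile_tree(triples)
print("policy as Boolean formula:")
print(" ", boolean_formula(tree))
print("pharmacist/treatment/codeine ->",
      evaluate_tree(tree, "codeine", "pharmacist", "treatment"))   # True
print("pharmacist/research/codeine  ->",
      evaluate_tree(tree, "codeine", "pharmacist", "research"))    # False: not granted
print("empty policy denies          ->",
      evaluate_tree(compile_tree([]), "codeine", "pharmacist", "treatment"))

# the same semantics through the deployed contract, with revocation
net = Network(seed=21)
patient = net.onboard_patient()
net.grant(patient, triples)
print("on-chain check:", net.evaluate(patient.address, "codeine",
                                      "pharmacist", "treatment"))
net.revoke(patient, [("codeine", "pharmacist", "treatment")])
print("after revocation:", net.evaluate(patient.address, "codeine",
                                        "pharmacist", "treatment"))
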