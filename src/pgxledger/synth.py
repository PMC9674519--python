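"""Synthetic fixtures: patient cohorts, PGx records and full scenarios.

Cohorts carry per-gene metaboliser/carrier phenotypes. CYP2D6 uses the
population frequencies the system is motivated by — 10% poor metabolisers,
2% ultra-rapid, with normal and intermediate collapsed into the 88%
residual class. The other pharmacogenes use rounded literature carrier
frequencies (HLA-B*57:01 ~6%, DPYD decreased-function ~5% intermediate /
0.5% poor, MT-RNR1 m.1555A>G ~0.2%); they exist so every guideline drug can
appear in fixtures and are not calibration targets.

A scenario registers users through the registration contract, publishes one
record per patient, grants each (drug, role, purpose) triple with
probability ``policy_density``, and scripts a mix of access attempts whose
ground-truth outcome (allow/deny) the generator retains — executed outcomes
must match it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import vocab
from .errors import GeneratorGap
from .network import FlowResult, Network, Wallet

CYP2D6_FREQS = {"poor": 0.10, "ultra_rapid": 0.02, "normal": 0.88}

PHENOTYPE_FREQS: dict[str, dict[str, float]] = {
    "CYP2D6": CYP2D6_FREQS,
    "HLA-B": {"positive": 0.06, "negative": 0.94},
    "DPYD": {"poor": 0.005, "intermediate": 0.05, "normal": 0.945},
    "MT-RNR1": {"positive": 0.002, "negative": 0.998},
}


@dataclass(frozen=True)
class PatientProfile:
    index: int
    phenotypes: dict[str, str]  # gene -> phenotype class

    @property
    def cyp2d6(self) -> str:
        return self.phenotypes["CYP2D6"]


def sample_patients(n: int, seed: int | np.random.Generator) -> list[PatientProfile]:
    """Sample *n* patients with per-gene phenotypes; reproducible under a
    fixed seed."""
    if n < 1:
        raise ValueError("need at least one patient")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = {}
    for gene, freqs in PHENOTYPE_FREQS.items():
        classes = list(freqs)
        draws[gene] = rng.choice(classes, size=n, p=[freqs[c] for c in classes])
    return [
        PatientProfile(i, {gene: str(draws[gene][i]) for gene in PHENOTYPE_FREQS})
        for i in range(n)
    ]


def guideline_recommendations(patient: PatientProfile) -> list[dict]:
    """Recommendation codes for every guideline drug, by table lookup on
    the patient's phenotypes."""
    out = []
    for drug in vocab.drugs():
        gene = vocab.gene_for(drug)
        phenotype = patient.phenotypes.get(gene)
        if phenotype is None:
            raise GeneratorGap(f"no phenotype sampled for gene {gene}")
        code = vocab.recommendation_for(drug, phenotype)
        if code is None:
            raise GeneratorGap(f"guideline table has no row for ({drug}, {phenotype})")
        out.append({"drug": drug, "gene": gene, "phenotype": phenotype,
                    "recommendation": code})
    return out


def make_pgx_record(patient: PatientProfile, patient_address: str, record_id: str,
                    rng: np.random.Generator, created_at: int = 0) -> tuple[dict, list[dict]]:
    """Build the off-chain record document and its on-chain recommendation
    list; the raw genomic payload is an opaque random blob."""
    recommendations = guideline_recommendations(patient)
    record = {
        "record_id": record_id,
        "patient": patient_address,
        "recommendations": recommendations,
        "raw_data": bytes(rng.bytes(64)).hex(),
        "created_at": created_at,
    }
    return record, recommendations


@dataclass
class ScriptedRequest:
    requester_index: int
    patient_index: int
    drug: str
    purpose: str
    expected_allow: bool
    expected_reason: str | None  # revert reason when denied


@dataclass
class Scenario:
    """A fully-initialised network plus the generator's ground truth."""

    seed: int
    network: Network
    patients: list[Wallet]
    profiles: list[PatientProfile]
    requesters: list[Wallet]
    creator: Wallet
    allow_sets: list[set[tuple[str, str, str]]]  # per patient
    requests: list[ScriptedRequest] = field(default_factory=list)

    def run_requests(self) -> list[tuple[ScriptedRequest, FlowResult]]:
        """Execute every scripted access attempt end to end."""
        out = []
        for req in self.requests:
            flow = self.network.request_flow(
                self.requesters[req.requester_index],
                self.patients[req.patient_index].address,
                req.drug, req.purpose)
            out.append((req, flow))
        return out

    def to_manifest(self) -> dict:
        return {
            "seed": self.seed,
            "n_patients": len(self.patients),
            "n_requesters": len(self.requesters),
            "patients": [w.address for w in self.patients],
            "requesters": [{"address": w.address, "label": w.label}
                           for w in self.requesters],
            "allow_sets": [sorted(map(list, s)) for s in self.allow_sets],
            "requests": [
                {"requester": r.requester_index, "patient": r.patient_index,
                 "drug": r.drug, "purpose": r.purpose,
                 "expected_allow": r.expected_allow}
                for r in self.requests
            ],
        }


def build_scenario(n_patients: int, n_requesters: int, policy_density: float,
                   seed: int, *, requests_per_requester: int = 2,
                   config: dict | None = None) -> Scenario:
    """Register users, publish records, set density-driven policies and
    script access attempts with known ground truth."""
    if n_patients < 1 or n_requesters < 1:
        raise ValueError("sizes must be >= 1")
    if not 0.0 <= policy_density <= 1.0:
        raise ValueError("policy_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    network = Network(seed=seed, config=config)
    creator = network.onboard_creator()
    profiles = sample_patients(n_patients, rng)
    patients = [network.onboard_patient(f"patient-{i}") for i in range(n_patients)]
    roles = vocab.roles()
    requesters = [
        network.onboard_requester(str(rng.choice(roles)), f"requester-{i}")
        for i in range(n_requesters)
    ]
    for i, (profile, wallet) in enumerate(zip(profiles, patients)):
        record, recommendations = make_pgx_record(
            profile, wallet.address, f"rec-{seed}-{i}", rng,
            created_at=network.node.now)
        network.publish_record(creator, record, recommendations)

    cube = vocab.all_triples()
    allow_sets: list[set[tuple[str, str, str]]] = []
    for wallet in patients:
        mask = rng.random(len(cube)) < policy_density
        allowed = {cube[j] for j in np.flatnonzero(mask)}
        allow_sets.append(allowed)
        if allowed:
            network.grant(wallet, sorted(allowed))

    requests = []
    requester_roles = [
        network.node.state.rsc["users"][w.address]["sub_role"] for w in requesters
    ]
    for ri in range(n_requesters):
        for _ in range(requests_per_requester):
            pi = int(rng.integers(n_patients))
            drug = str(rng.choice(vocab.drugs()))
            purpose = str(rng.choice(vocab.purposes()))
            triple = (drug, requester_roles[ri], purpose)
            allowed = triple in allow_sets[pi]
            requests.append(ScriptedRequest(
                requester_index=ri, patient_index=pi, drug=drug, purpose=purpose,
                expected_allow=allowed,
                expected_reason=None if allowed else "PERMISSION_DENIED"))
    return Scenario(seed=seed, network=network, patients=patients,
                    profiles=profiles, requesters=requesters, creator=creator,
                    allow_sets=allow_sets, requests=requests)
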