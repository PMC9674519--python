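"""Access-control manager: policies, tickets, tokens, eURL pipeline."""

from __future__ import annotations

import numpy as np
import pytest

from pgxledger import vocab

CUBE = vocab.all_triples()


def _eval(net, patient_addr, drug, role, purpose):
    receipt = net.call(net.owner, "ACMSC", "evaluatePolicy",
                       {"patient": patient_addr, "drug": drug, "role": role,
                        "purpose": purpose})
    return receipt.result["allow"]


class TestPolicies:
    def test_worked_example_grants_exactly_one_triple(self, clinic):
        """Codeine data accessible by a pharmacist for treatment; the other
        53 combinations stay denied."""
        net, patient = clinic["net"], clinic["patient"]
        net.grant(patient, [("codeine", "pharmacist", "treatment")])
        assert _eval(net, patient.address, "codeine", "pharmacist", "treatment")
        allowed = [t for t in CUBE if _eval(net, patient.address, *t)]
        assert allowed == [("codeine", "pharmacist", "treatment")]

    def test_empty_policy_denies_all_requests(self, clinic):
        net, patient = clinic["net"], clinic["patient"]
        receipt = net.call(clinic["pharmacist"], "ACMSC", "requestAccessTicket",
                           {"patient": patient.address, "drug": "codeine",
                            "purpose": "treatment"})
        assert receipt.reason == "PERMISSION_DENIED"

    def test_random_grants_match_membership_exhaustively(self, clinic):
        net, patient = clinic["net"], clinic["patient"]
        rng = np.random.default_rng(9)
        chosen = {CUBE[i] for i in rng.choice(len(CUBE), size=5, replace=False)}
        net.grant(patient, sorted(chosen))
        for triple in CUBE:
            assert _eval(net, patient.address, *triple) == (triple in chosen)

    def test_unknown_patient_denies(self, net):
        assert not _eval(net, "0x" + "9" * 40, "codeine", "pharmacist", "treatment")

    def test_bad_vocabulary_code_reverts(self, clinic):
        receipt = clinic["net"].call(
            clinic["patient"], "ACMSC", "setAccessPermission",
            {"triples": [{"drug": "aspirin", "role": "pharmacist",
                          "purpose": "treatment"}]})
        assert receipt.reason == "BAD_TRIPLE"

    def test_non_patient_cannot_set_policy(self, clinic):
        receipt = clinic["net"].call(
            clinic["pharmacist"], "ACMSC", "setAccessPermission",
            {"triples": [{"drug": "codeine", "role": "pharmacist",
                          "purpose": "treatment"}]})
        assert receipt.reason == "AUTH_ONLY_PATIENT"

    def test_paper_spelling_alias_accepted(self, clinic):
        receipt = clinic["net"].must_call(
            clinic["patient"], "ACMSC", "setAcessPermission",
            {"triples": [{"drug": "codeine", "role": "pharmacist",
                          "purpose": "treatment"}]})
        assert receipt.status == "succeeded"


class TestRevocation:
    def test_revocation_denies_the_very_next_request(self, clinic):
        net, patient = clinic["net"], clinic["patient"]
        net.grant(patient, [("codeine", "pharmacist", "treatment")])
        net.revoke(patient, [("codeine", "pharmacist", "treatment")])
        receipt = net.call(clinic["pharmacist"], "ACMSC", "requestAccessTicket",
                           {"patient": patient.address, "drug": "codeine",
                            "purpose": "treatment"})
        assert receipt.reason == "PERMISSION_DENIED"

    def test_cancelling_an_ungranted_triple_is_a_noop(self, clinic):
        receipt = clinic["net"].revoke(clinic["patient"],
                                       [("abacavir", "researcher", "research")])
        assert receipt.result["removed"] == 0

    def test_random_interleavings_end_at_set_membership(self, clinic):
        net, patient = clinic["net"], clinic["patient"]
        rng = np.random.default_rng(11)
        model: set = set()
        for _ in range(40):
            triple = CUBE[int(rng.integers(len(CUBE)))]
            if rng.random() < 0.5:
                net.grant(patient, [triple])
                model.add(triple)
            else:
                net.revoke(patient, [triple])
                model.discard(triple)
        for triple in CUBE:
            assert _eval(net, patient.address, *triple) == (triple in model)

    def test_removing_triples_never_enlarges_the_accept_set(self, clinic):
        net, patient = clinic["net"], clinic["patient"]
        rng = np.random.default_rng(13)
        start = {CUBE[i] for i in rng.choice(len(CUBE), size=12, replace=False)}
        net.grant(patient, sorted(start))
        accepted_before = {t for t in CUBE if _eval(net, patient.address, *t)}
        victims = sorted(start)[:5]
        net.revoke(patient, victims)
        accepted_after = {t for t in CUBE if _eval(net, patient.address, *t)}
        assert accepted_after <= accepted_before
        assert accepted_after == accepted_before - set(victims)


class TestTicketsAndTokens:
    def _grant_and_ticket(self, clinic, role="pharmacist"):
        net, patient = clinic["net"], clinic["patient"]
        net.grant(patient, [("codeine", role, "treatment")])
        requester = clinic[role]
        receipt = net.must_call(requester, "ACMSC", "requestAccessTicket",
                                {"patient": patient.address, "drug": "codeine",
                                 "purpose": "treatment"})
        return requester, receipt.result["ticket_id"]

    def test_allowed_triple_yields_live_ticket(self, clinic):
        _, ticket_id = self._grant_and_ticket(clinic)
        ticket = clinic["net"].node.state.acmsc["tickets"][ticket_id]
        assert not ticket["consumed"]
        assert ticket["expires_at"] > clinic["net"].node.now

    def test_requester_role_comes_from_registry_not_request(self, clinic):
        """A physician asking under a pharmacist-only policy is denied."""
        net, patient = clinic["net"], clinic["patient"]
        net.grant(patient, [("codeine", "pharmacist", "treatment")])
        receipt = net.call(clinic["physician"], "ACMSC", "requestAccessTicket",
                           {"patient": patient.address, "drug": "codeine",
                            "purpose": "treatment"})
        assert receipt.reason == "PERMISSION_DENIED"

    def test_drug_absent_from_metadata_reverts(self, clinic):
        net, patient = clinic["net"], clinic["patient"]
        other = net.onboard_patient("no-record")  # registered, no metadata
        net.grant(other, [("codeine", "pharmacist", "treatment")])
        receipt = net.call(clinic["pharmacist"], "ACMSC", "requestAccessTicket",
                           {"patient": other.address, "drug": "codeine",
                            "purpose": "treatment"})
        assert receipt.reason == "NO_METADATA_FOR_DRUG"

    def test_ticket_single_use(self, clinic):
        requester, ticket_id = self._grant_and_ticket(clinic)
        net = clinic["net"]
        net.must_call(requester, "ACMSC", "requestAccessToken",
                      {"ticket_id": ticket_id})
        second = net.call(requester, "ACMSC", "requestAccessToken",
                          {"ticket_id": ticket_id})
        assert second.reason == "TICKET_CONSUMED"

    def test_ticket_expiry_boundary(self, clinic):
        """Ticket valid at expiry−1, dead at expiry and expiry+1."""
        net = clinic["net"]
        for offset, expected in ((-1, "succeeded"), (0, "TICKET_EXPIRED"),
                                 (1, "TICKET_EXPIRED")):
            requester, ticket_id = self._grant_and_ticket(clinic)
            expires = net.node.state.acmsc["tickets"][ticket_id]["expires_at"]
            net.node.now = expires + offset
            receipt = net.call(requester, "ACMSC", "requestAccessToken",
                               {"ticket_id": ticket_id})
            got = receipt.status if receipt.status == "succeeded" else receipt.reason
            assert got == expected, f"offset {offset}"

    def test_ticket_belongs_to_its_requester(self, clinic):
        _, ticket_id = self._grant_and_ticket(clinic)
        receipt = clinic["net"].call(clinic["physician"], "ACMSC",
                                     "requestAccessToken", {"ticket_id": ticket_id})
        assert receipt.reason == "AUTH_NOT_TICKET_OWNER"

    def test_token_is_one_time(self, clinic):
        requester, ticket_id = self._grant_and_ticket(clinic)
        net = clinic["net"]
        token_id = net.must_call(requester, "ACMSC", "requestAccessToken",
                                 {"ticket_id": ticket_id}).result["token_id"]
        net.must_call(requester, "ACMSC", "requestData", {"token_id": token_id})
        replayed = net.call(requester, "ACMSC", "requestData",
                            {"token_id": token_id})
        assert replayed.reason == "TOKEN_USED"

    def test_token_of_a_is_useless_to_b(self, clinic):
        requester, ticket_id = self._grant_and_ticket(clinic)
        net = clinic["net"]
        token_id = net.must_call(requester, "ACMSC", "requestAccessToken",
                                 {"ticket_id": ticket_id}).result["token_id"]
        receipt = net.call(clinic["physician"], "ACMSC", "requestData",
                           {"token_id": token_id})
        assert receipt.reason == "AUTH_NOT_TOKEN_OWNER"


class TestEncryptedUrl:
    def test_fetch_before_store_not_ready(self, clinic):
        net, patient = clinic["net"], clinic["patient"]
        net.grant(patient, [("codeine", "pharmacist", "treatment")])
        requester = clinic["pharmacist"]
        ticket = net.must_call(requester, "ACMSC", "requestAccessTicket",
                               {"patient": patient.address, "drug": "codeine",
                                "purpose": "treatment"}).result
        token_id = net.must_call(requester, "ACMSC", "requestAccessToken",
                                 {"ticket_id": ticket["ticket_id"]}).result["token_id"]
        net.must_call(requester, "ACMSC", "requestData", {"token_id": token_id})
        receipt = net.call(requester, "ACMSC", "fetchEncryptedUrl",
                           {"token_id": token_id})
        assert receipt.reason == "EURL_NOT_READY"

    def test_only_oracle_may_store(self, clinic):
        receipt = clinic["net"].call(clinic["pharmacist"], "ACMSC",
                                     "storeEncryptedUrl",
                                     {"token_id": "t", "ciphertext": "00",
                                      "recipient": clinic["pharmacist"].address})
        assert receipt.reason == "AUTH_ONLY_ORACLE"

    @pytest.mark.parametrize("round_", range(5))
    def test_eurl_fetch_is_one_time(self, clinic, round_):
        net, patient = clinic["net"], clinic["patient"]
        net.grant(patient, [("codeine", "pharmacist", "treatment")])
        flow = net.request_flow(clinic["pharmacist"], patient.address,
                                "codeine", "treatment")
        assert flow.ok
        second = net.call(clinic["pharmacist"], "ACMSC", "fetchEncryptedUrl",
                          {"token_id": flow.token_id})
        assert second.reason == "EURL_ALREADY_FETCHED"

    def test_release_leaves_complete_ordered_trace(self, clinic):
        """Every successful release shows TicketIssued → TokenIssued →
        DataRequested → URLStored, in order, for the same pair."""
        net, patient = clinic["net"], clinic["patient"]
        net.grant(patient, [("codeine", "pharmacist", "treatment")])
        flow = net.request_flow(clinic["pharmacist"], patient.address,
                                "codeine", "treatment")
        assert flow.ok
        events = [e for e in net.node.get_events(contract="ACMSC")
                  if e.payload.get("patient") == patient.address]
        names = [e.name for e in events]
        order = [names.index(n) for n in
                 ("TicketIssued", "TokenIssued", "DataRequested", "URLStored")]
        assert order == sorted(order)
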