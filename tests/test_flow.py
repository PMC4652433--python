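import numpy as np
import pytest

from famrisk.errors import IncompleteFlowError, IntakeError
from famrisk.flow import (
    GROUP_KEYS,
    NAMED_ROLES,
    PageKind,
    answer,
    answers_for,
    blank_form,
    diagram_intake,
    flow_to_pedigree,
    form_for,
    render_summary,
    reset_form,
    run_flow,
    start_flow,
)
from famrisk.pedigree import CancerHistory, Pedigree, Relative, RelativeRole, validate
from conftest import random_pedigree

ALL_NEGATIVE = [{"affected": False}] * 6 + [{"count": 0}] * 4 + [{"action": "submit"}]


def detail(age=None, relation=None, **flags):
    payload = {
        "age_dx": age,
        "multiple_polyps": flags.get("polyps", False),
        "other_cancers": flags.get("other", False),
        "multiple_crc": flags.get("multi", False),
    }
    if relation:
        payload["relation"] = relation
    return payload


class TestTraversalStructure:
    def test_flow_starts_at_mother_screening(self):
        state = start_flow()
        assert state.current.target == ("mother", 0)
        assert state.current.kind is PageKind.SCREEN_NAMED
        assert state.pages_presented == 1

    def test_base_sequence_order_and_length(self):
        """6 named screens, 4 group counts, then the terminal confirm page."""
        state = start_flow()
        seen = []
        for payload in ALL_NEGATIVE:
            seen.append(state.current.kind)
            state = answer(state, payload)
        assert state.finished
        assert seen == [PageKind.SCREEN_NAMED] * 6 + [PageKind.GROUP_COUNT] * 4 + [PageKind.CONFIRM]
        assert state.pages_presented == 11

    def test_minimal_traversal_is_eleven_pages(self):
        state = run_flow(ALL_NEGATIVE)
        assert state.finished and state.pages_presented == 11
        assert len(flow_to_pedigree(state)) == 0

    def test_maximal_traversal_is_forty_five_pages(self):
        payloads = []
        for _ in NAMED_ROLES:
            payloads += [{"affected": True}, detail(60)]
        for key in GROUP_KEYS:
            relation = "aunt_uncle" if key in ("maternal_group", "paternal_group") else None
            payloads.append({"count": 7})
            payloads += [detail(60, relation=relation)] * 7
        payloads.append({"action": "submit"})
        state = run_flow(payloads)
        assert state.finished and state.pages_presented == 45

    def test_only_mother_affirmative_is_twelve_pages(self):
        payloads = (
            [{"affected": True}, detail(60)]
            + [{"affected": False}] * 5
            + [{"count": 0}] * 4
            + [{"action": "submit"}]
        )
        state = run_flow(payloads)
        assert state.pages_presented == 12
        ped = flow_to_pedigree(state)
        assert ped.relatives == (
            Relative(RelativeRole.MOTHER, 0, CancerHistory(True, 60)),
        )

    def test_group_count_expands_to_detail_pages(self):
        payloads = (
            [{"affected": False}] * 6
            + [{"count": 2}, detail(47, relation="aunt_uncle"), detail(62, relation="aunt_uncle")]
            + [{"count": 0}] * 3
            + [{"action": "submit"}]
        )
        state = run_flow(payloads)
        assert state.pages_presented == 13
        ped = flow_to_pedigree(state)
        assert [r.history.age_at_diagnosis for r in ped] == [47, 62]
        assert {r.role for r in ped} == {RelativeRole.MATERNAL_AUNT_UNCLE}
        assert [r.member_index for r in ped] == [0, 1]

    def test_restart_from_confirm_recounts_pages(self):
        state = run_flow(ALL_NEGATIVE[:-1])
        assert state.current.kind is PageKind.CONFIRM
        state = answer(state, {"action": "restart"})
        assert state.current.target == ("mother", 0)
        assert state.answers == ()
        assert state.pages_presented == 12
        for payload in ALL_NEGATIVE:
            state = answer(state, payload)
        # 11 pages before the restart, then the full 11-page base again;
        # the final submit does not present a further page
        assert state.finished and state.pages_presented == 22


class TestPayloadValidation:
    def test_bad_screen_payload_rejected(self):
        state = start_flow()
        with pytest.raises(IntakeError):
            answer(state, {"affected": "yes"})
        # the immutable state is unchanged and still usable
        assert answer(state, {"affected": False}).pages_presented == 2

    def test_count_above_cap_rejected(self):
        state = run_flow([{"affected": False}] * 6)
        with pytest.raises(IntakeError):
            answer(state, {"count": 8})
        with pytest.raises(IntakeError):
            answer(state, {"count": -1})

    def test_detail_requires_relation_for_side_groups(self):
        state = run_flow([{"affected": False}] * 6 + [{"count": 1}])
        assert state.current.kind is PageKind.DETAIL
        with pytest.raises(IntakeError):
            answer(state, detail(50))

    def test_pedigree_needs_finished_flow(self):
        with pytest.raises(IncompleteFlowError):
            flow_to_pedigree(start_flow())

    def test_answer_after_submit_rejected(self):
        state = run_flow(ALL_NEGATIVE)
        with pytest.raises(IncompleteFlowError):
            answer(state, {"affected": False})


class TestDiagramIntake:
    def test_empty_form_empty_pedigree(self):
        assert len(diagram_intake(blank_form())) == 0

    def test_missing_block_listed(self):
        form = blank_form()
        del form["father"], form["siblings"]
        with pytest.raises(IntakeError, match="father"):
            diagram_intake(form)

    def test_reset_requires_confirmation(self):
        form = blank_form()
        form["mother"] = {"affected": True, "age_dx": 60}
        assert reset_form(form, confirm=False)["mother"]["affected"] is True
        wiped = reset_form(form, confirm=True)
        assert wiped["mother"] == {"affected": False}
        assert len(diagram_intake(wiped)) == 0

    def test_form_with_father_matches_flow(self):
        form = blank_form()
        form["father"] = {"affected": True, "age_dx": 50}
        from_form = diagram_intake(form)
        payloads = (
            [{"affected": False}, {"affected": True}, detail(50)]
            + [{"affected": False}] * 4
            + [{"count": 0}] * 4
            + [{"action": "submit"}]
        )
        from_flow = flow_to_pedigree(run_flow(payloads))
        assert from_form == from_flow


class TestModeEquivalenceAndSummary:
    def test_modes_agree_on_random_pedigrees(self, rng):
        """Both intake modes reproduce any pedigree, with byte-identical summaries."""
        for _ in range(100):
            ped = random_pedigree(rng).canonical()
            via_flow = flow_to_pedigree(run_flow(answers_for(ped)))
            via_form = diagram_intake(form_for(ped))
            assert via_flow == via_form == ped
            assert render_summary(via_flow).text() == render_summary(via_form).text()

    def test_summary_empty_pedigree(self):
        report = render_summary(Pedigree())
        assert report.assessment.category.value == "average"
        text = report.text()
        assert "Average lifetime risk" in text
        assert "No affected relatives entered." in text

    def test_summary_lists_entries_and_category(self, mother_at_60):
        text = render_summary(mother_at_60).text()
        assert "Mother: affected by bowel cancer; diagnosed at age 60" in text
        assert "Slightly increased risk" in text
        assert "general practitioner" in text

    def test_no_answer_loss(self, rng):
        """Every affirmative answer surfaces as a summary entry line."""
        for _ in range(30):
            ped = random_pedigree(rng).canonical()
            report = render_summary(ped)
            assert len(report.entries) == len(ped)


class TestRandomTraversalProperties:
    @staticmethod
    def random_traversal(rng):
        state = start_flow()
        while not state.finished:
            page = state.current
            if page.kind is PageKind.SCREEN_NAMED:
                payload = {"affected": bool(rng.random() < 0.5)}
            elif page.kind is PageKind.GROUP_COUNT:
                payload = {"count": int(rng.integers(0, 8))}
            elif page.kind is PageKind.DETAIL:
                relation = None
                if "relation" in page.fields:
                    relation = "aunt_uncle" if rng.random() < 0.5 else "child"
                age = None if rng.random() < 0.3 else int(rng.integers(30, 90))
                payload = detail(age, relation=relation, polyps=bool(rng.random() < 0.1))
            else:
                payload = {"action": "submit"}
            state = answer(state, payload)
        return state

    def test_page_count_bounds_and_valid_pedigrees(self, rng):
        """Every traversal terminates within the 11..45 page bounds and yields
        a valid pedigree whose size matches the affirmative answers."""
        for _ in range(200):
            state = self.random_traversal(rng)
            assert 11 <= state.pages_presented <= 45
            ped = flow_to_pedigree(state)
            assert validate(ped).ok
            n_details = sum(
                1 for page, _ in state.answers if page.kind is PageKind.DETAIL
            )
            assert len(ped) == n_details
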