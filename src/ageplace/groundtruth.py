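"""Scoring of the ground-truthing matching exercise.

Validation panellists receive anonymised cluster maps of places they
know (clusters shown only as colours) together with the cluster names
and pen portraits, and match each colour to a supergroup. Accuracy per
supergroup — overall and by participant type — measures how
recognisable each cluster's description is on the ground.
"""

from __future__ import annotations

import pandas as pd

PARTICIPANT_TYPES = ("external", "student")


def score_responses(
    responses: pd.DataFrame,
    key: pd.DataFrame,
    supergroups: list[str] | None = None,
) -> pd.DataFrame:
    """Accuracy (%) per supergroup for external, student and all participants.

    ``responses`` columns: ``participant_id, participant_type, location,
    colour, choice`` (the supergroup code the participant assigned to
    that colour; missing/blank choices count as incorrect attempts).
    ``key`` columns: ``location, colour, supergroup`` (the truth).

    Every response location must appear in the key; a non-missing choice
    that is not a known supergroup code raises. Returns a frame indexed
    by supergroup with columns ``external, student, all`` (unrounded
    percentages) plus attempt counts.
    """
    for col in ("participant_id", "participant_type", "location", "colour", "choice"):
        if col not in responses.columns:
            raise ValueError(f"responses missing column {col!r}")
    bad_type = set(responses["participant_type"]) - set(PARTICIPANT_TYPES)
    if bad_type:
        raise ValueError(f"unknown participant types: {sorted(bad_type)}")
    known = set(key["supergroup"].astype(str))
    if supergroups is not None:
        known |= set(map(str, supergroups))
    choices = responses["choice"].dropna().astype(str)
    unknown = set(choices) - known
    if unknown:
        raise ValueError(f"responses contain unknown supergroup codes: {sorted(unknown)}")

    merged = responses.merge(key, on=["location", "colour"], how="left")
    if merged["supergroup"].isna().any():
        missing = merged.loc[
            merged["supergroup"].isna(), ["location", "colour"]
        ].drop_duplicates()
        raise ValueError(
            f"response locations/colours absent from answer key: "
            f"{missing.to_records(index=False).tolist()}"
        )
    merged["correct"] = (
        merged["choice"].astype("string") == merged["supergroup"].astype("string")
    ).fillna(False)

    def _acc(sub: pd.DataFrame) -> float:
        return 100.0 * sub["correct"].sum() / len(sub) if len(sub) else float("nan")

    codes = sorted(set(merged["supergroup"].astype(str)), key=str)
    rows = []
    for sg in codes:
        sub = merged.loc[merged["supergroup"].astype(str) == sg]
        ext = sub.loc[sub["participant_type"] == "external"]
        stu = sub.loc[sub["participant_type"] == "student"]
        rows.append(
            {
                "supergroup": sg,
                "external": _acc(ext),
                "student": _acc(stu),
                "all": _acc(sub),
                "n_external": len(ext),
                "n_student": len(stu),
                "n_all": len(sub),
            }
        )
    return pd.DataFrame(rows).set_index("supergroup")
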