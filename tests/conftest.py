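"""Shared fixtures: tiny hand-built SRS tables in both dialects."""

import pandas as pd
import pytest

from srsignal.simulate import default_sim_config, simulate_reports


@pytest.fixture
def jader_tables() -> dict[str, pd.DataFrame]:
    """Three-case JADER-dialect table set with known structure.

    Case JP1: male 60s, pemafibrate (suspect) + aspirin (concomitant),
    two events (one biliary) with complete dates.
    Case JP2: female 40s, fenofibrate spelling variant, one event.
    Case JP3: unknown demographics, no drugs/events.
    """
    demo = pd.DataFrame(
        {
            "識別番号": ["JP1", "JP2", "JP3"],
            "性別": ["男性", "女性", ""],
            "年齢": ["60歳代", "40歳代", ""],
            "身長": ["160cm台", "150cm台", ""],
            "体重": ["60kg台", "70kg台", ""],
            "報告者職種": ["医療関係者", "消費者", ""],
            "報告年": ["2022", "2021", "2020"],
        }
    )
    drug = pd.DataFrame(
        {
            "識別番号": ["JP1", "JP1", "JP2"],
            "医薬品連番": ["1", "2", "1"],
            "医薬品の関与": ["被疑薬", "併用薬", "被疑薬"],
            "医薬品（一般名）": ["ペマフィブラート", "ASPIRIN", "フェノフィブラート"],
            "投与開始日": ["20220110", "202201", "20210601"],
            "投与終了日": ["", "", ""],
        }
    )
    reac = pd.DataFrame(
        {
            "識別番号": ["JP1", "JP1", "JP2"],
            "有害事象": ["Cholelithiasis", "Nausea", "Rash"],
            "有害事象コード": ["10008629", "10028813", "10037844"],
            "発現日": ["20220301", "20220215", "202107"],
        }
    )
    hist = pd.DataFrame(columns=["識別番号", "有害事象", "有害事象コード", "発現日"])
    return {"demo": demo, "drug": drug, "reac": reac, "hist": hist}


@pytest.fixture
def faers_tables() -> dict[str, pd.DataFrame]:
    """Two-case FAERS-dialect table set, one case with two versions."""
    demo = pd.DataFrame(
        {
            "primaryid": ["1001", "1002", "2001"],
            "caseid": ["100", "100", "200"],
            "caseversion": ["1", "2", "1"],
            "event_dt": ["20230310", "20230310", "202302"],
            "sex": ["M", "M", "F"],
            "age": ["65", "65", "42"],
            "age_cod": ["YR", "YR", "YR"],
            "wt": ["72", "72", ""],
            "wt_cod": ["KG", "KG", ""],
            "occp_cod": ["MD", "MD", "CN"],
            "fda_dt": ["20230401", "20230501", "20230315"],
        }
    )
    drug = pd.DataFrame(
        {
            "primaryid": ["1002", "1002", "2001"],
            "caseid": ["100", "100", "200"],
            "drug_seq": ["1", "2", "1"],
            "role_cod": ["PS", "C", "SS"],
            "drugname": ["PEMAFIBRATE", "ASPIRIN", "FENOFIBRIC ACID"],
        }
    )
    reac = pd.DataFrame(
        {
            "primaryid": ["1002", "1002", "2001"],
            "caseid": ["100", "100", "200"],
            "pt": ["Cholelithiasis", "Nausea", "Rash"],
        }
    )
    ther = pd.DataFrame(
        {
            "primaryid": ["1002", "2001"],
            "caseid": ["100", "200"],
            "dsg_drug_seq": ["1", "1"],
            "start_dt": ["20230105", "20230110"],
            "end_dt": ["", ""],
        }
    )
    outc = pd.DataFrame(
        {
            "primaryid": ["1002", "2001"],
            "caseid": ["100", "200"],
            "outc_cod": ["OT", "HO"],
        }
    )
    return {"demo": demo, "drug": drug, "reac": reac, "ther": ther, "outc": outc}


@pytest.fixture(scope="session")
def small_sim():
    """A 5000-report synthetic draw with a known pemafibrate association."""
    cfg = default_sim_config(
        seed=42,
        n_reports=5000,
        theta={("pemafibrate", "10008629"): 4.0},
    )
    return simulate_reports(cfg)
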