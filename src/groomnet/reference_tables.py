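"""Bundled encodings of the published study-population and period tables.

The study deposited no raw scan data, but its two descriptive tables — the
roster of 18 sanctuary chimpanzees with their background covariates, and the
chronology of the 18 observation time periods for the Mutamba and Bilinga
groups — are printed in full and serve as fixed inputs for bookkeeping
checks and as the default period plan of the synthetic-data generator.

Periods are printed with observation-phase years only; here each period
spans its phase years as half-open ISO date intervals [Jan 1, Jan 1).
"""

from __future__ import annotations

import io

import pandas as pd

#: Roster of the 18 study subjects: sex, origin (wild-caught vs captive
#: born), predominant housing condition during infancy (with vs without
#: conspecifics), and age category at arrival at the sanctuary.
ROSTER_CSV = """\
id,sex,origin,phc_infant,arrival_age_cat
AFR,F,wild,without_conspecifics,subadult
BEA,F,wild,with_conspecifics,adult
BON,M,captive,with_conspecifics,subadult
CHA,M,captive,with_conspecifics,subadult
CHE,F,wild,without_conspecifics,adult
COC,F,wild,without_conspecifics,adult
JUA,M,captive,with_conspecifics,subadult
MAR,M,captive,with_conspecifics,adult
NIC,M,captive,without_conspecifics,subadult
PAN,M,captive,with_conspecifics,subadult
ROM,F,wild,with_conspecifics,adult
SAR,F,captive,without_conspecifics,subadult
TIC,M,wild,without_conspecifics,adult
TOM,M,wild,with_conspecifics,adult
TON,M,wild,with_conspecifics,adult
TOT,M,wild,with_conspecifics,adult
VIC,M,captive,without_conspecifics,adult
WAT,F,captive,with_conspecifics,subadult
"""

#: Chronology of the 18 observation time periods (M1-M6 Mutamba, B1-B12
#: Bilinga) with group composition and stable/unstable labels.
PERIODS_CSV = """\
code,group,start_date,end_date,stability,members
M1,Mutamba,2006-01-01,2008-01-01,stable,MAR;CHA;TON;PAN
M2,Mutamba,2008-01-01,2009-01-01,unstable,MAR;CHA;TON;BON
M3,Mutamba,2008-01-01,2012-01-01,stable,MAR;CHA;TON;BON
M4,Mutamba,2012-01-01,2018-01-01,stable,MAR;CHA;TON;BON;JUA
M5,Mutamba,2017-01-01,2018-01-01,unstable,MAR;CHA;TON;BON;JUA;AFR;WAT
M6,Mutamba,2018-01-01,2019-01-01,stable,MAR;CHA;TON;BON;JUA;AFR;WAT
B1,Bilinga,2006-01-01,2008-01-01,stable,TOT;ROM;WAT;BON;SAR;JUA;NIC
B2,Bilinga,2010-01-01,2011-01-01,unstable,TOT;ROM;WAT;SAR;JUA;NIC;TIC;VIC;AFR
B3,Bilinga,2010-01-01,2011-01-01,unstable,TOT;ROM;WAT;SAR;JUA;NIC;TIC;VIC;AFR
B4,Bilinga,2011-01-01,2012-01-01,stable,TOT;WAT;SAR;JUA;NIC;TIC;VIC;AFR
B5,Bilinga,2011-01-01,2012-01-01,unstable,TOT;WAT;SAR;NIC;TIC;VIC;AFR
B6,Bilinga,2012-01-01,2013-01-01,unstable,TOT;WAT;NIC;TIC;VIC;AFR
B7,Bilinga,2012-01-01,2013-01-01,unstable,TOT;WAT;NIC;TIC;VIC;AFR
B8,Bilinga,2013-01-01,2014-01-01,unstable,WAT;NIC;TIC;VIC;AFR
B9,Bilinga,2013-01-01,2016-01-01,unstable,WAT;NIC;TIC;VIC;AFR;TOM;COC;BEA
B10,Bilinga,2017-01-01,2018-01-01,unstable,WAT;NIC;TIC;VIC;AFR;TOM;COC;BEA;CHE
B11,Bilinga,2017-01-01,2018-01-01,unstable,NIC;TIC;VIC;TOM;COC;BEA;CHE
B12,Bilinga,2018-01-01,2019-01-01,stable,NIC;TIC;VIC;TOM;COC;BEA;CHE
"""

#: Published counts of scans retained after filtering for grooming-given,
#: per social group and overall.
FILTERED_SCAN_TOTALS = {
    "Bilinga": 197_053,
    "Mutamba": 106_070,
    "overall": 303_123,
}


def roster_frame() -> pd.DataFrame:
    """Return the study roster as a DataFrame in the roster.csv dialect."""
    return pd.read_csv(io.StringIO(ROSTER_CSV))


def periods_frame() -> pd.DataFrame:
    """Return the study period chronology in the periods.csv dialect."""
    return pd.read_csv(io.StringIO(PERIODS_CSV))
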