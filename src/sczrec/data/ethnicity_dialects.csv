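raw_label,category
WHITE,White
WHITE - RUSSIAN,White
WHITE - EASTERN EUROPEAN,White
WHITE - OTHER EUROPEAN,White
WHITE - BRAZILIAN,White
PORTUGUESE,White
BLACK/AFRICAN AMERICAN,Black/African American
BLACK/AFRICAN,Black/African American
BLACK/CARIBBEAN ISLAND,Black/African American
BLACK/CAPE VERDEAN,Black/African American
BLACK,Black/African American
HISPANIC OR LATINO,Hispanic/Latino
HISPANIC/LATINO,Hispanic/Latino
HISPANIC/LATINO - PUERTO RICAN,Hispanic/Latino
HISPANIC/LATINO - DOMINICAN,Hispanic/Latino
HISPANIC/LATINO - CUBAN,Hispanic/Latino
HISPANIC/LATINO - MEXICAN,Hispanic/Latino
HISPANIC/LATINO - GUATEMALAN,Hispanic/Latino
HISPANIC/LATINO - SALVADORAN,Hispanic/Latino
HISPANIC/LATINO - HONDURAN,Hispanic/Latino
HISPANIC/LATINO - CENTRAL AMERICAN,Hispanic/Latino
HISPANIC/LATINO - COLUMBIAN,Hispanic/Latino
HISPANIC/LATINO - SOUTH AMERICAN,Hispanic/Latino
SOUTH AMERICAN,Hispanic/Latino
ASIAN,Asian
ASIAN - CHINESE,Asian
ASIAN - KOREAN,Asian
ASIAN - ASIAN INDIAN,Asian
ASIAN - SOUTH EAST ASIAN,Asian
UNKNOWN,EXCLUDE
UNKNOWN/NOT SPECIFIED,EXCLUDE
UNABLE TO OBTAIN,EXCLUDE
PATIENT DECLINED TO ANSWER,EXCLUDE
OTHER,EXCLUDE
AMERICAN INDIAN/ALASKA NATIVE,EXCLUDE
NATIVE HAWAIIAN OR OTHER PACIFIC ISLANDER,EXCLUDE
MULTIPLE RACE/ETHNICITY,EXCLUDE
MULTIRACIAL,EXCLUDE
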