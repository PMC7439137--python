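level,code,name,example_titles,lead_statement,main_duties,employment_requirements
1,0,Management occupations,,,,
1,1,"Business, finance, and administration occupations",,,,
1,2,Natural and applied sciences and related occupations,,,,
1,3,Health occupations,,,,
1,4,"Occupations in education, law and social, community, and government services",,,,
1,5,"Occupations in art, culture, recreation, and sport",,,,
1,6,Sales and service occupations,,,,
1,7,"Trades, transport, and equipment operators and related occupations",,,,
1,8,"Natural resources, agriculture, and related production occupations",,,,
1,9,Occupations in manufacturing and utilities,,,,
2,00,senior management occupations,,,,
2,40,professional occupations in education services,,,,
3,001,legislators and senior management,,,,
3,403,secondary and elementary school teachers and educational counsellors,,,,
4,0011,legislators,legislators,,,
4,0012,senior government managers and officials,senior government managers and officials,,,
4,0013,"senior managers: financial, communications, and other business services","senior managers: financial, communications, and other business services",,,
4,0014,"senior managers: health, education, social and community services, and membership organizations","senior managers: health, education, social and community services, and membership organizations",,,
4,0015,"senior managers: trade, broadcasting, and other services, n.e.c (not elsewhere classified)","senior managers: trade, broadcasting, and other services, n.e.c (not elsewhere classified)",,,
4,0016,"senior managers: construction, transportation, production, and utilities","senior managers: construction, transportation, production, and utilities",,,
4,4031,secondary school teachers,secondary school teachers,,,
4,4032,elementary school and kindergarten teachers,elementary school and kindergarten teachers,,,
4,4033,educational counsellors,educational counsellors,,,
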