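species	sector	n_sites	n_individuals
Amara dux Tschitscherine, 1894	desert	3	6
Amara dux Tschitscherine, 1894	typical_1	8	11
Amara dux Tschitscherine, 1894	typical_2	6	10
Amara dux Tschitscherine, 1894	typical_3	9	31
Amara dux Tschitscherine, 1894	meadow_1	0	0
Amara dux Tschitscherine, 1894	meadow_2	6	9
Amara harpaloides Dejean, 1828	desert	1	7
Amara harpaloides Dejean, 1828	typical_1	0	0
Amara harpaloides Dejean, 1828	typical_2	3	3
Amara harpaloides Dejean, 1828	typical_3	0	0
Amara harpaloides Dejean, 1828	meadow_1	0	0
Amara harpaloides Dejean, 1828	meadow_2	1	1
Amara helva Tschitscherine, 1898	desert	3	9
Amara helva Tschitscherine, 1898	typical_1	0	0
Amara helva Tschitscherine, 1898	typical_2	0	0
Amara helva Tschitscherine, 1898	typical_3	0	0
Amara helva Tschitscherine, 1898	meadow_1	0	0
Amara helva Tschitscherine, 1898	meadow_2	0	0
Amara sp.	desert	0	0
Amara sp.	typical_1	2	3
Amara sp.	typical_2	4	6
Amara sp.	typical_3	0	0
Amara sp.	meadow_1	1	1
Amara sp.	meadow_2	4	5
Broscus kozlovi Kryzhanovskij, 1995	desert	0	0
Broscus kozlovi Kryzhanovskij, 1995	typical_1	1	2
Broscus kozlovi Kryzhanovskij, 1995	typical_2	0	0
Broscus kozlovi Kryzhanovskij, 1995	typical_3	0	0
Broscus kozlovi Kryzhanovskij, 1995	meadow_1	1	1
Broscus kozlovi Kryzhanovskij, 1995	meadow_2	3	5
Calosoma anthrax Semenov, 1900	desert	0	0
Calosoma anthrax Semenov, 1900	typical_1	9	17
Calosoma anthrax Semenov, 1900	typical_2	7	11
Calosoma anthrax Semenov, 1900	typical_3	5	6
Calosoma anthrax Semenov, 1900	meadow_1	0	0
Calosoma anthrax Semenov, 1900	meadow_2	5	7
Calosoma chinense Kirby, 1819	desert	1	1
Calosoma chinense Kirby, 1819	typical_1	1	1
Calosoma chinense Kirby, 1819	typical_2	0	0
Calosoma chinense Kirby, 1819	typical_3	0	0
Calosoma chinense Kirby, 1819	meadow_1	0	0
Calosoma chinense Kirby, 1819	meadow_2	1	1
Calosoma lugens Chaudoir, 1869	desert	0	0
Calosoma lugens Chaudoir, 1869	typical_1	4	6
Calosoma lugens Chaudoir, 1869	typical_2	2	3
Calosoma lugens Chaudoir, 1869	typical_3	0	0
Calosoma lugens Chaudoir, 1869	meadow_1	0	0
Calosoma lugens Chaudoir, 1869	meadow_2	2	2
Carabus anchocephalus Reitter, 1896	desert	0	0
Carabus anchocephalus Reitter, 1896	typical_1	1	1
Carabus anchocephalus Reitter, 1896	typical_2	3	3
Carabus anchocephalus Reitter, 1896	typical_3	11	25
Carabus anchocephalus Reitter, 1896	meadow_1	0	0
Carabus anchocephalus Reitter, 1896	meadow_2	14	56
Carabus crassesculptus Kraatz, 1881	desert	0	0
Carabus crassesculptus Kraatz, 1881	typical_1	0	0
Carabus crassesculptus Kraatz, 1881	typical_2	0	0
Carabus crassesculptus Kraatz, 1881	typical_3	0	0
Carabus crassesculptus Kraatz, 1881	meadow_1	15	295
Carabus crassesculptus Kraatz, 1881	meadow_2	11	44
Carabus gigoloides Cavazzuti, 2000	desert	0	0
Carabus gigoloides Cavazzuti, 2000	typical_1	0	0
Carabus gigoloides Cavazzuti, 2000	typical_2	0	0
Carabus gigoloides Cavazzuti, 2000	typical_3	0	0
Carabus gigoloides Cavazzuti, 2000	meadow_1	14	266
Carabus gigoloides Cavazzuti, 2000	meadow_2	1	1
Carabus glyptoterus Fischer Von Waldheim, 1827	desert	15	252
Carabus glyptoterus Fischer Von Waldheim, 1827	typical_1	14	66
Carabus glyptoterus Fischer Von Waldheim, 1827	typical_2	14	194
Carabus glyptoterus Fischer Von Waldheim, 1827	typical_3	15	327
Carabus glyptoterus Fischer Von Waldheim, 1827	meadow_1	0	0
Carabus glyptoterus Fischer Von Waldheim, 1827	meadow_2	14	47
Carabus modestulus Semenov, 1887	desert	0	0
Carabus modestulus Semenov, 1887	typical_1	0	0
Carabus modestulus Semenov, 1887	typical_2	0	0
Carabus modestulus Semenov, 1887	typical_3	0	0
Carabus modestulus Semenov, 1887	meadow_1	15	82
Carabus modestulus Semenov, 1887	meadow_2	1	2
Carabus sculptipennis Chaudoir, 1877	desert	0	0
Carabus sculptipennis Chaudoir, 1877	typical_1	15	247
Carabus sculptipennis Chaudoir, 1877	typical_2	14	140
Carabus sculptipennis Chaudoir, 1877	typical_3	6	14
Carabus sculptipennis Chaudoir, 1877	meadow_1	2	2
Carabus sculptipennis Chaudoir, 1877	meadow_2	1	1
Carabus vladimirskyi Dejean, 1830	desert	1	3
Carabus vladimirskyi Dejean, 1830	typical_1	15	560
Carabus vladimirskyi Dejean, 1830	typical_2	15	639
Carabus vladimirskyi Dejean, 1830	typical_3	6	13
Carabus vladimirskyi Dejean, 1830	meadow_1	15	808
Carabus vladimirskyi Dejean, 1830	meadow_2	10	16
Corsyra fusula (Fischer Von Waldheim, 1820)	desert	1	3
Corsyra fusula (Fischer Von Waldheim, 1820)	typical_1	0	0
Corsyra fusula (Fischer Von Waldheim, 1820)	typical_2	0	0
Corsyra fusula (Fischer Von Waldheim, 1820)	typical_3	0	0
Corsyra fusula (Fischer Von Waldheim, 1820)	meadow_1	0	0
Corsyra fusula (Fischer Von Waldheim, 1820)	meadow_2	0	0
Cymindis binotata Fischer Von Waldheim, 1820	desert	7	19
Cymindis binotata Fischer Von Waldheim, 1820	typical_1	0	0
Cymindis binotata Fischer Von Waldheim, 1820	typical_2	0	0
Cymindis binotata Fischer Von Waldheim, 1820	typical_3	0	0
Cymindis binotata Fischer Von Waldheim, 1820	meadow_1	0	0
Cymindis binotata Fischer Von Waldheim, 1820	meadow_2	0	0
Dolichus halensis (Schaller, 1783)	desert	0	0
Dolichus halensis (Schaller, 1783)	typical_1	0	0
Dolichus halensis (Schaller, 1783)	typical_2	1	2
Dolichus halensis (Schaller, 1783)	typical_3	1	1
Dolichus halensis (Schaller, 1783)	meadow_1	0	0
Dolichus halensis (Schaller, 1783)	meadow_2	0	0
Harpalus lumbaris Mannerheim, 1825	desert	4	11
Harpalus lumbaris Mannerheim, 1825	typical_1	0	0
Harpalus lumbaris Mannerheim, 1825	typical_2	0	0
Harpalus lumbaris Mannerheim, 1825	typical_3	0	0
Harpalus lumbaris Mannerheim, 1825	meadow_1	0	0
Harpalus lumbaris Mannerheim, 1825	meadow_2	0	0
Poecilus fortipes (Chaudoir, 1850)	desert	0	0
Poecilus fortipes (Chaudoir, 1850)	typical_1	15	227
Poecilus fortipes (Chaudoir, 1850)	typical_2	14	103
Poecilus fortipes (Chaudoir, 1850)	typical_3	6	8
Poecilus fortipes (Chaudoir, 1850)	meadow_1	13	120
Poecilus fortipes (Chaudoir, 1850)	meadow_2	15	94
Poecilus gebleri (Dejean, 1828)	desert	0	0
Poecilus gebleri (Dejean, 1828)	typical_1	15	391
Poecilus gebleri (Dejean, 1828)	typical_2	15	608
Poecilus gebleri (Dejean, 1828)	typical_3	15	135
Poecilus gebleri (Dejean, 1828)	meadow_1	2	2
Poecilus gebleri (Dejean, 1828)	meadow_2	7	9
Pseudotaphoxenus mongolicus (Jedlicka, 1953)	desert	11	23
Pseudotaphoxenus mongolicus (Jedlicka, 1953)	typical_1	3	4
Pseudotaphoxenus mongolicus (Jedlicka, 1953)	typical_2	10	39
Pseudotaphoxenus mongolicus (Jedlicka, 1953)	typical_3	4	11
Pseudotaphoxenus mongolicus (Jedlicka, 1953)	meadow_1	0	0
Pseudotaphoxenus mongolicus (Jedlicka, 1953)	meadow_2	0	0
Pseudotaphoxenus rugupennis (Faldermann, 1836)	desert	3	3
Pseudotaphoxenus rugupennis (Faldermann, 1836)	typical_1	15	85
Pseudotaphoxenus rugupennis (Faldermann, 1836)	typical_2	15	133
Pseudotaphoxenus rugupennis (Faldermann, 1836)	typical_3	15	39
Pseudotaphoxenus rugupennis (Faldermann, 1836)	meadow_1	6	11
Pseudotaphoxenus rugupennis (Faldermann, 1836)	meadow_2	12	39
Reflexisphodrus reflexipennis (Semenov, 1889)	desert	0	0
Reflexisphodrus reflexipennis (Semenov, 1889)	typical_1	1	2
Reflexisphodrus reflexipennis (Semenov, 1889)	typical_2	0	0
Reflexisphodrus reflexipennis (Semenov, 1889)	typical_3	0	0
Reflexisphodrus reflexipennis (Semenov, 1889)	meadow_1	14	332
Reflexisphodrus reflexipennis (Semenov, 1889)	meadow_2	10	34
Zabrus potanini Semenov, 1889	desert	1	1
Zabrus potanini Semenov, 1889	typical_1	10	25
Zabrus potanini Semenov, 1889	typical_2	11	54
Zabrus potanini Semenov, 1889	typical_3	0	0
Zabrus potanini Semenov, 1889	meadow_1	7	16
Zabrus potanini Semenov, 1889	meadow_2	10	20
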