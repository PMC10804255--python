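icd_version,prefix,category
10,T36,poisoning
10,T37,poisoning
10,T38,poisoning
10,T39,poisoning
10,T40,poisoning
10,T41,poisoning
10,T42,poisoning
10,T43,poisoning
10,T44,poisoning
10,T45,poisoning
10,T46,poisoning
10,T47,poisoning
10,T48,poisoning
10,T49,poisoning
10,T50,poisoning
10,T51,poisoning
10,T52,poisoning
10,T53,poisoning
10,T54,poisoning
10,T55,poisoning
10,T56,poisoning
10,T57,poisoning
10,T58,poisoning
10,T59,poisoning
10,T60,poisoning
10,T61,poisoning
10,T62,poisoning
10,T63,poisoning
10,T64,poisoning
10,T65,poisoning
10,X72,firearm
10,X73,firearm
10,X74,firearm
10,X78,cutting_piercing
10,X79,cutting_piercing
10,X80,jumping
10,X81,jumping
9,965,poisoning
9,967,poisoning
9,969,poisoning
9,E950,poisoning
9,E951,poisoning
9,E952,poisoning
9,E953,hanging_strangulation_suffocation
9,E955,firearm
9,E956,cutting_piercing
9,881,cutting_piercing
9,E957,jumping
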