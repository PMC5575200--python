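region,country,locality,haplotype,count
native,China,Heibei/Beijing,H1,75
native,China,Heibei/Beijing,H2,1
native,China,Heibei/Beijing,H3,14
native,China,Heibei/Beijing,H4,1
native,China,Heibei/Beijing,H5,1
native,China,Heibei/Beijing,H6,1
native,China,Heibei/Beijing,H7,1
native,China,Heibei/Beijing,H10,1
native,China,Heibei/Beijing,H11,1
native,China,Heibei/Beijing,H12,1
native,China,Heibei/Beijing,H13,1
native,China,Heibei/Beijing,H14,1
native,China,Heibei/Beijing,H15,1
native,China,Heibei/Beijing,H16,1
native,China,Heibei/Beijing,H17,1
native,China,Heibei/Beijing,H18,1
native,China,Heibei/Beijing,H19,1
native,China,Heibei/Beijing,H20,1
native,China,Heibei/Beijing,H21,1
native,China,Xi'an,H1,1
native,China,Xi'an,H33,2
native,China,Xi'an,H45,1
native,China,Xi'an,H53,2
native,China,Nanjing,H2,5
native,China,Nanjing,H3,1
native,China,Nanjing,H22,2
native,China,Nanjing,H26,2
native,China,Nanjing,H34,1
native,China,Nanjing,H55,1
native,China,Anhui Prov.,H1,3
native,China,Anhui Prov.,H2,1
native,China,Anhui Prov.,H3,4
native,China,Anhui Prov.,H33,1
native,China,Fuzhou,H1,7
native,China,Haidain,H1,5
native,China,Haidain,H46,1
native,China,Hefei,H22,4
native,China,Hefei,H54,3
native,China,Kunming,H1,1
native,China,Kunming,H17,4
native,Japan,Tsubuka,H9,1
native,Japan,Tsubuka,H23,1
native,Japan,Tsubuka,H24,1
native,Japan,Tsubuka,H27,1
native,Japan,Tsubuka,H39,1
native,Japan,Tsubuka,H41,4
native,Japan,Tsubuka,H44,2
native,Japan,Tsubuka,H45,5
native,Japan,Yokote,H27,1
native,Japan,Yokote,H39,2
native,Japan,Yokote,H40,2
native,Japan,Yokote,H41,1
native,Japan,Yokote,H42,1
native,Japan,Yokote,H49,1
native,Japan,Yokote,H50,1
native,Japan,Yokote,H51,3
native,Japan,Yokote,H57,1
native,Japan,Yuzawa,H1,1
native,Japan,Yuzawa,H23,1
native,Japan,Yuzawa,H39,1
native,Japan,Yuzawa,H40,4
native,Japan,Yuzawa,H43,1
native,Japan,Yuzawa,H48,1
native,Japan,Yuzawa,H51,5
native,Japan,Yuzawa,H52,1
native,Republic of Korea,Yangpyeong,H22,1
native,Republic of Korea,Suwon,H2,1
native,Republic of Korea,Suwon,H22,1
native,Republic of Korea,Suwon,H25,1
native,Republic of Korea,Suwon,H38,1
native,Republic of Korea,Chungcheong Province,H28,1
native,Republic of Korea,Chungcheong Province,H35,1
native,Republic of Korea,Chungcheong Province,H36,1
native,Republic of Korea,Chungcheong Province,H37,1
native,Republic of Korea,East Seoul,H22,1
native,Republic of Korea,East Seoul,H29,1
native,Republic of Korea,Anyang,H22,1
introduced,United States,New Jersey,H1,14
introduced,United States,Maryland,H1,14
introduced,United States,Georgia,H1,6
introduced,United States,Delaware,H1,3
introduced,United States,Massachusetts,H1,2
introduced,United States,Mississippi,H1,2
introduced,United States,New York,H1,2
introduced,United States,Pennsylvania,H1,6
introduced,United States,Virginia,H1,6
introduced,United States,West Virginia,H1,6
introduced,United States,Ohio,H1,4
introduced,United States,Michigan,H1,5
introduced,United States,California,H1,11
introduced,United States,California,H3,1
introduced,United States,California,H7,1
introduced,United States,Oregon,H1,1
introduced,United States,Oregon,H3,10
introduced,United States,Oregon,H23,1
introduced,United States,Oregon,H47,9
introduced,United States,Washington,H3,2
introduced,United States,Washington,H47,2
introduced,Canada,Canada,H1,49
introduced,Canada,Canada,H6,1
introduced,Canada,Canada,H14,1
introduced,Switzerland,North Switzerland,H3,162
introduced,Switzerland,North Switzerland,H8,30
introduced,Switzerland,North Switzerland,H9,1
introduced,Switzerland,Lugano,H1,2
introduced,Switzerland,Lugano,H3,25
introduced,Switzerland,Lugano,H8,1
introduced,Switzerland,Ticino,H3,2
introduced,Italy,Emilia-Romagna,H1,31
introduced,Italy,Lombardy,H1,1
introduced,Italy,Lombardy,H3,7
introduced,Italy,Lombardy,H8,1
introduced,France,Schiltigheim,H1,1
introduced,France,Schiltigheim,H3,136
introduced,France,Schiltigheim,H8,2
introduced,Hungary,Budapest,H1,83
introduced,Hungary,Budapest,H3,1
introduced,Greece,Athens,H1,18
introduced,Greece,Athens,H3,4
introduced,Greece,Athens,H22,2
introduced,Greece,Athens,H30,1
introduced,Greece,Athens,H31,1
introduced,Greece,Athens,H32,8
introduced,Greece,Athens,H33,23
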