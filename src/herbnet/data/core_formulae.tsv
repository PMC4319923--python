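formula_id	name	syndrome	herb
F1	Xuefu Zhuyu Decoction	Heart-blood stagnation	Persicae Semen
F1	Xuefu Zhuyu Decoction	Heart-blood stagnation	Carthami Flos
F1	Xuefu Zhuyu Decoction	Heart-blood stagnation	Angelicae Sinensis Radix
F1	Xuefu Zhuyu Decoction	Heart-blood stagnation	Paeoniae Radix Rubra
F1	Xuefu Zhuyu Decoction	Heart-blood stagnation	Rehmanniae Radix
F1	Xuefu Zhuyu Decoction	Heart-blood stagnation	Chuanxiong Rhizoma
F1	Xuefu Zhuyu Decoction	Heart-blood stagnation	Aurantii Fructus
F1	Xuefu Zhuyu Decoction	Heart-blood stagnation	Platycodonis Radix
F1	Xuefu Zhuyu Decoction	Heart-blood stagnation	Bupleuri Radix
F1	Xuefu Zhuyu Decoction	Heart-blood stagnation	Achyranthis Bidentatae Radix
F1	Xuefu Zhuyu Decoction	Heart-blood stagnation	Glycyrrhizae Radix et Rhizoma
F2	Gualou Xiebai Banxia Decoction	Phlegm-blood stasis syndrome	Trichosanthis Fructus
F2	Gualou Xiebai Banxia Decoction	Phlegm-blood stasis syndrome	Allii Macrostemonis Bulbus
F2	Gualou Xiebai Banxia Decoction	Phlegm-blood stasis syndrome	Pinelliae Rhizoma
F3	Buyang Huanwu Decoction	Qi deficiency and blood stagnation	Astragali Radix
F3	Buyang Huanwu Decoction	Qi deficiency and blood stagnation	Angelicae Sinensis Radix
F3	Buyang Huanwu Decoction	Qi deficiency and blood stagnation	Paeoniae Radix Rubra
F3	Buyang Huanwu Decoction	Qi deficiency and blood stagnation	Pheretima
F3	Buyang Huanwu Decoction	Qi deficiency and blood stagnation	Chuanxiong Rhizoma
F3	Buyang Huanwu Decoction	Qi deficiency and blood stagnation	Carthami Flos
F3	Buyang Huanwu Decoction	Qi deficiency and blood stagnation	Persicae Semen
F4	Guanxin Suhe Pills	Cold congelating	Styrax
F4	Guanxin Suhe Pills	Cold congelating	Santali Albi Lignum
F4	Guanxin Suhe Pills	Cold congelating	Aucklandiae Radix
F4	Guanxin Suhe Pills	Cold congelating	Borneolum
F4	Guanxin Suhe Pills	Cold congelating	Olibanum
F5	Zhenwu Decoction	Yang deficiency of heart and kidney	Poria
F5	Zhenwu Decoction	Yang deficiency of heart and kidney	Paeoniae Radix Alba
F5	Zhenwu Decoction	Yang deficiency of heart and kidney	Atractylodis Macrocephalae Rhizoma
F5	Zhenwu Decoction	Yang deficiency of heart and kidney	Zingiberis Rhizoma Recens
F5	Zhenwu Decoction	Yang deficiency of heart and kidney	Aconiti Lateralis Radix Praeparata
F6	Tianwang Buxin Dan	Yin deficiency of heart and kidney	Asparagi Radix
F6	Tianwang Buxin Dan	Yin deficiency of heart and kidney	Ginseng Radix et Rhizoma
F6	Tianwang Buxin Dan	Yin deficiency of heart and kidney	Poria
F6	Tianwang Buxin Dan	Yin deficiency of heart and kidney	Scrophulariae Radix
F6	Tianwang Buxin Dan	Yin deficiency of heart and kidney	Salviae Miltiorrhizae Radix et Rhizoma
F6	Tianwang Buxin Dan	Yin deficiency of heart and kidney	Polygalae Radix
F6	Tianwang Buxin Dan	Yin deficiency of heart and kidney	Platycodonis Radix
F6	Tianwang Buxin Dan	Yin deficiency of heart and kidney	Angelicae Sinensis Radix
F6	Tianwang Buxin Dan	Yin deficiency of heart and kidney	Schisandrae Chinensis Fructus
F6	Tianwang Buxin Dan	Yin deficiency of heart and kidney	Ophiopogonis Radix
F6	Tianwang Buxin Dan	Yin deficiency of heart and kidney	Platycladi Semen
F6	Tianwang Buxin Dan	Yin deficiency of heart and kidney	Ziziphi Spinosae Semen
F6	Tianwang Buxin Dan	Yin deficiency of heart and kidney	Rehmanniae Radix
F7	Shengmai San	Qi-Yin deficiency	Ginseng Radix et Rhizoma
F7	Shengmai San	Qi-Yin deficiency	Ophiopogonis Radix
F7	Shengmai San	Qi-Yin deficiency	Schisandrae Chinensis Fructus
F8	Huoluo Xiaolin Dan	Qi-blood stagnation	Angelicae Sinensis Radix
F8	Huoluo Xiaolin Dan	Qi-blood stagnation	Salviae Miltiorrhizae Radix et Rhizoma
F8	Huoluo Xiaolin Dan	Qi-blood stagnation	Olibanum
F8	Huoluo Xiaolin Dan	Qi-blood stagnation	Myrrha
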