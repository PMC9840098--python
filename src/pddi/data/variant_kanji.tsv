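# variant (itaiji) character pairs: standard form, variant form
# char	variant
高	髙
崎	﨑
沢	澤
辺	邊
斎	齋
斉	齊
浜	濱
国	國
真	眞
広	廣
島	嶋
富	冨
徳	德
恵	惠
黒	黑
竜	龍
与	與
桜	櫻
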