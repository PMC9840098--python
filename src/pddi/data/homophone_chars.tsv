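# kana-conversion (IME homophone) substitution table: character, reading,
# comma-separated alternative characters with the same reading
# char	reading	alternatives
裕	ゆう	祐,優,悠
祐	ゆう	裕,佑
幸	こう	孝,康
翔	しょう	祥,昭
健	けん	賢,謙
陽	よう	洋,庸
直	なお	尚
美	み	実,未
恵	え	絵,江
香	か	佳,加
智	ち	知
和	かず	一
正	まさ	雅,政
誠	せい	成
浩	こう	宏,弘
隆	たか	貴,孝
藤	とう	東
田	た	多
中	なか	仲
井	い	伊
本	もと	元
川	かわ	河
村	むら	邑
橋	はし	箸
森	もり	守
山	やま	矢間
丁	ちょう	町
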