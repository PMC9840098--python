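# family name lexicon: kanji, reading (kana), optional alternative reading,
# optional homophone spelling (different kanji, same reading)
# kanji	kana	alt_kana	homophone_kanji
佐藤	さとう
鈴木	すずき
高橋	たかはし
田中	たなか
伊藤	いとう	いふじ	井藤
渡辺	わたなべ		渡部
山本	やまもと
中村	なかむら
小林	こばやし
加藤	かとう		嘉藤
吉田	よしだ	きちだ
山田	やまだ
佐々木	ささき
山口	やまぐち
松本	まつもと
井上	いのうえ
木村	きむら
斉藤	さいとう		斎藤
清水	しみず	きよみず
山崎	やまざき	やまさき
河野	こうの	かわの
阿部	あべ		安部
森	もり
池田	いけだ	いけた
橋本	はしもと
石川	いしかわ
中島	なかじま	なかしま	中嶋
前田	まえだ	まえた
藤田	ふじた
後藤	ごとう		五藤
長谷川	はせがわ
村上	むらかみ
近藤	こんどう
石井	いしい
坂本	さかもと		阪本
遠藤	えんどう
青木	あおき
藤井	ふじい
西村	にしむら
福田	ふくだ	ふくた
太田	おおた		大田
三浦	みうら
岡本	おかもと
松田	まつだ	まつた
中田	なかた	なかだ
東	ひがし	あずま
角田	つのだ	かくた
新谷	しんたに	あらや
羽田	はた	はねだ
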