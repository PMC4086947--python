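<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{% block title %}{% endblock %}</title>
</head>
<body>
<h1>{% block heading %}{% endblock %}</h1>
{% block content %}{% endblock %}
</body>
</html>
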